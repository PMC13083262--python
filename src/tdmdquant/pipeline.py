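"""Small-RNA read processing: adapter trimming, quality filtering, 13-nt prefix
mapping with collapsing, and 13-31-nt isoform tabulation.

The mapping strategy is deliberately simple and exact: the first 13 nt of each
trimmed read are string-matched against the dictionary; species sharing a 13-nt
prefix are collapsed into a single entry, and the full read length (13-31 nt)
defines the isoform. No mismatches, indels or genome alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from tdmdquant.dictionary import PREFIX_LEN, MirnaDictionary, normalize_seq

LENGTH_MIN = 13
LENGTH_MAX = 31

#: provenance counter names, in reporting order
COUNTER_FIELDS = (
    "total",
    "adapter_rejected",
    "quality_rejected",
    "too_short",
    "too_long",
    "unassigned",
    "assigned",
)


# --------------------------------------------------------------------------- #
# collapsed prefix index
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class CollapsedEntry:
    collapsed_name: str
    members: tuple[str, ...]


@dataclass
class CollapsedIndex:
    """Maps each distinct 13-nt prefix to its collapsed dictionary entry."""

    entries: dict[str, CollapsedEntry]

    def lookup(self, prefix: str) -> CollapsedEntry | None:
        return self.entries.get(prefix)

    def collapsed_names(self) -> list[str]:
        return [e.collapsed_name for e in self.entries.values()]

    def collapsed_name_of(self, species_name: str) -> str | None:
        for e in self.entries.values():
            if species_name in e.members:
                return e.collapsed_name
        return None


def build_collapsed_index(dictionary: MirnaDictionary) -> CollapsedIndex:
    """Group species by their first 13 nt (U/T-normalized).

    Species sharing a prefix — including processing variants — become one
    entry whose name joins all member names with "/" in dictionary order.
    """
    groups: dict[str, list[str]] = {}
    for sp in dictionary:
        if len(sp.sequence) < PREFIX_LEN:  # defensive; MirnaSpecies enforces it
            raise ValueError(f"species {sp.name!r} shorter than {PREFIX_LEN} nt")
        groups.setdefault(sp.prefix13, []).append(sp.name)
    entries = {
        prefix: CollapsedEntry("/".join(names), tuple(names))
        for prefix, names in groups.items()
    }
    return CollapsedIndex(entries)


# --------------------------------------------------------------------------- #
# per-read operations
# --------------------------------------------------------------------------- #
def trim_adapter(
    seq: str,
    qual: str,
    adapter: str,
    min_overlap: int = 4,
    max_mismatch_rate: float = 0.0,
) -> tuple[str, str] | None:
    """Remove the leftmost adapter occurrence and everything 3' of it.

    The adapter may be present in full anywhere in the read, or as a prefix of
    the adapter overlapping the read's 3' end by at least ``min_overlap``
    bases. Up to ``floor(max_mismatch_rate * overlap)`` mismatches are
    tolerated. Returns ``(insert, insert_quality)`` or ``None`` when no
    adapter is found (the read is rejected).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(qual) != len(seq):
        raise ValueError("quality string length differs from sequence length")
    read = normalize_seq(seq)
    ad = normalize_seq(adapter)
    n, m = len(read), len(ad)
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(max_mismatch_rate * overlap)
        mism = 0
        for a, b in zip(read[i : i + overlap], ad[:overlap]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return seq[:i], qual[:i]
    return None


def quality_filter(seq: str, qual: str, q_threshold: int = 30) -> bool:
    """Keep a read iff its mean base quality strictly exceeds ``q_threshold``.

    Quality strings are Phred+33. Raises on sequence/quality length mismatch.
    """
    if len(qual) != len(seq):
        raise ValueError("quality string length differs from sequence length")
    if not seq:
        return False
    mean_q = float(np.mean([ord(c) - 33 for c in qual]))
    return mean_q > q_threshold


def assign_read(
    insert: str, index: CollapsedIndex
) -> tuple[str, str | None, int | None]:
    """Assign a trimmed insert to a collapsed entry by exact 13-nt prefix match.

    Returns ``(status, collapsed_name, length)`` where status is one of
    ``"assigned"``, ``"unassigned"``, ``"too_short"``, ``"too_long"``.
    The isoform length is the full insert length.
    """
    insert = normalize_seq(insert)
    if len(insert) < LENGTH_MIN:
        return ("too_short", None, None)
    entry = index.lookup(insert[:PREFIX_LEN])
    if entry is None:
        return ("unassigned", None, None)
    if len(insert) > LENGTH_MAX:
        return ("too_long", entry.collapsed_name, len(insert))
    return ("assigned", entry.collapsed_name, len(insert))


# --------------------------------------------------------------------------- #
# count table
# --------------------------------------------------------------------------- #
@dataclass
class IsoformCountTable:
    """Read counts indexed by (collapsed miRNA, length 13-31 nt, sample).

    ``counts`` is a wide integer DataFrame with a (mirna, length) MultiIndex
    and one column per sample; ``counters`` holds per-sample provenance
    (total reads and every rejection class), so that
    assigned + rejected classes = total per sample.
    """

    counts: pd.DataFrame
    counters: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.nlevels != 2:
            raise ValueError("counts must be indexed by (mirna, length)")
        self.counts.index = self.counts.index.set_names(["mirna", "length"])
        lengths = self.counts.index.get_level_values("length")
        if len(lengths) and (lengths.min() < LENGTH_MIN or lengths.max() > LENGTH_MAX):
            raise ValueError(f"isoform lengths must lie in [{LENGTH_MIN},{LENGTH_MAX}]")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counters is None:
            self.counters = pd.DataFrame(
                0, index=self.samples, columns=list(COUNTER_FIELDS)
            )
            self.counters["total"] = self.counters["assigned"] = self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def conservation_ok(self) -> bool:
        """Per sample: assigned + all rejection counters == total."""
        parts = self.counters[list(COUNTER_FIELDS[1:])].sum(axis=1)
        return bool((parts == self.counters["total"]).all())

    # --------------------------------------------------------------- I/O
    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_2": "sample"})
        )
        long.columns = ["mirna", "length", "sample", "count"]
        return long

    @classmethod
    def from_long(
        cls, long: pd.DataFrame, samples: Sequence[str] | None = None
    ) -> "IsoformCountTable":
        wide = (
            long.pivot_table(
                index=["mirna", "length"],
                columns="sample",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .astype(int)
        )
        wide.columns.name = None
        if samples is not None:
            wide = wide.reindex(columns=list(samples), fill_value=0)
        return cls(wide)

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    def counters_to_tsv(self, path: str | Path) -> None:
        self.counters.rename_axis("sample").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IsoformCountTable":
        return cls.from_long(pd.read_csv(path, sep="\t"))

    def sorted(self) -> "IsoformCountTable":
        return IsoformCountTable(self.counts.sort_index(), self.counters.copy())

    def equals(self, other: "IsoformCountTable") -> bool:
        a = self.counts.sort_index()
        b = other.counts.reindex(columns=a.columns).sort_index()
        # ignore all-zero rows on either side
        a = a[a.sum(axis=1) > 0]
        b = b[b.sum(axis=1) > 0]
        return a.equals(b)


def tabulate_isoforms(
    per_sample: Mapping[str, Iterable[tuple[str, int]]]
    | Sequence[tuple[str, Iterable[tuple[str, int]]]],
    counters: Mapping[str, Mapping[str, int]] | None = None,
) -> IsoformCountTable:
    """Aggregate per-sample (collapsed_name, length) assignments into a table.

    ``per_sample`` maps sample name to its assignment stream (or is a sequence
    of such pairs; duplicate sample names are an error). ``counters``
    optionally supplies the per-sample provenance counters from upstream
    filtering; when omitted, totals equal assigned counts.
    """
    if isinstance(per_sample, Mapping):
        items = list(per_sample.items())
    else:
        items = list(per_sample)
    names = [s for s, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate sample names")

    rows: dict[tuple[str, int], dict[str, int]] = {}
    for sample, assignments in items:
        for name, length in assignments:
            if not (LENGTH_MIN <= length <= LENGTH_MAX):
                raise ValueError(f"length {length} outside [{LENGTH_MIN},{LENGTH_MAX}]")
            cell = rows.setdefault((name, length), {})
            cell[sample] = cell.get(sample, 0) + 1

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["mirna", "length"])
    counts = pd.DataFrame(0, index=index, columns=names, dtype=int)
    for key, cell in rows.items():
        for sample, n in cell.items():
            counts.loc[key, sample] = n

    ctr = pd.DataFrame(0, index=names, columns=list(COUNTER_FIELDS))
    assigned = counts.sum(axis=0) if len(counts) else pd.Series(0, index=names)
    ctr["assigned"] = assigned
    if counters is not None:
        for sample, c in counters.items():
            for k, v in c.items():
                ctr.loc[sample, k] = v
    else:
        ctr["total"] = ctr["assigned"]
    return IsoformCountTable(counts, ctr)


# --------------------------------------------------------------------------- #
# whole-pipeline driver
# --------------------------------------------------------------------------- #
def process_fastq(
    fastq_paths: Sequence[str | Path],
    dictionary: MirnaDictionary,
    adapter: str,
    sample_names: Sequence[str] | None = None,
    q_threshold: int = 30,
    min_overlap: int = 4,
    max_mismatch_rate: float = 0.0,
) -> IsoformCountTable:
    """Run trim -> quality filter -> prefix assignment over FASTQ files.

    One sample per file; sample names default to the file stems. Reads without
    a detectable adapter are discarded (counted as adapter_rejected).
    """
    if sample_names is None:
        sample_names = [Path(p).stem for p in fastq_paths]
    if len(sample_names) != len(set(sample_names)):
        raise ValueError("duplicate sample names")
    index = build_collapsed_index(dictionary)

    assignments: dict[str, list[tuple[str, int]]] = {}
    counters: dict[str, dict[str, int]] = {}
    for path, sample in zip(fastq_paths, sample_names):
        asg: list[tuple[str, int]] = []
        ctr = {k: 0 for k in COUNTER_FIELDS}
        with open(path) as fh:
            for _title, seq, qual in FastqGeneralIterator(fh):
                ctr["total"] += 1
                trimmed = trim_adapter(seq, qual, adapter, min_overlap, max_mismatch_rate)
                if trimmed is None:
                    ctr["adapter_rejected"] += 1
                    continue
                insert, iqual = trimmed
                if not insert:
                    ctr["too_short"] += 1
                    continue
                if not quality_filter(insert, iqual, q_threshold):
                    ctr["quality_rejected"] += 1
                    continue
                status, name, length = assign_read(insert, index)
                if status == "assigned":
                    ctr["assigned"] += 1
                    asg.append((name, length))
                else:
                    ctr[status] += 1
        assignments[sample] = asg
        counters[sample] = ctr
    return tabulate_isoforms(assignments, counters)
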