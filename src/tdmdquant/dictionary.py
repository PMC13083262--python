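"""miRNA dictionaries: species records, guide/passenger linkage, FASTA/TSV I/O.

Sequences are stored in DNA space (U normalized to T, uppercase) so that reads
and references hash identically; mapping is prefix-exact, so the alphabet
convention only has to be consistent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PREFIX_LEN = 13

_VALID_ARMS = {"5p", "3p"}
_VALID_ROLES = {"mature", "passenger"}


def normalize_seq(seq: str) -> str:
    """Uppercase and convert U to T (RNA and DNA treated as equivalent)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MirnaSpecies:
    """One miRNA species (a mature guide, a passenger strand, or a processing variant).

    Parameters
    ----------
    name : unique identifier within a dictionary.
    sequence : reference sequence, >= 13 nt (DNA or RNA alphabet).
    hairpin_id : identifier of the precursor hairpin; links guides to the
        passenger strands co-produced from the same hairpin.
    arm : which hairpin arm the species derives from, ``"5p"`` or ``"3p"``.
    role : ``"mature"`` (guide) or ``"passenger"``.
    variant_of : name of the parent species when this entry is a processing
        variant (e.g. an alternative annotation of the same guide).
    context_3p : templated nucleotides immediately downstream of the 3' end in
        the hairpin, used to build length isoforms longer than the reference.
    """

    name: str
    sequence: str
    hairpin_id: str
    arm: str
    role: str
    variant_of: str | None = None
    context_3p: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        object.__setattr__(self, "context_3p", normalize_seq(self.context_3p))
        if len(self.sequence) < PREFIX_LEN:
            raise ValueError(
                f"species {self.name!r}: sequence shorter than {PREFIX_LEN} nt"
            )
        if self.arm not in _VALID_ARMS:
            raise ValueError(f"species {self.name!r}: arm must be one of {_VALID_ARMS}")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"species {self.name!r}: role must be one of {_VALID_ROLES}")

    @property
    def prefix13(self) -> str:
        return self.sequence[:PREFIX_LEN]


@dataclass
class MirnaDictionary:
    """Ordered registry of miRNA species with guide/passenger linkage."""

    species: list[MirnaSpecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species names in dictionary")
        self._by_name = {s.name: s for s in self.species}

    def __iter__(self) -> Iterator[MirnaSpecies]:
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)

    def __getitem__(self, name: str) -> MirnaSpecies:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def add(self, sp: MirnaSpecies) -> None:
        if sp.name in self._by_name:
            raise ValueError(f"duplicate species name {sp.name!r}")
        self.species.append(sp)
        self._by_name[sp.name] = sp

    def matures(self) -> list[MirnaSpecies]:
        return [s for s in self.species if s.role == "mature"]

    def passengers_of(self, mature_name: str) -> list[MirnaSpecies]:
        """Passenger strands sharing the hairpin of a mature species."""
        hp = self._by_name[mature_name].hairpin_id
        return [s for s in self.species if s.role == "passenger" and s.hairpin_id == hp]

    # ------------------------------------------------------------------ I/O
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s.sequence), id=s.name, description="") for s in self.species
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_tsv(self, path: str | Path) -> None:
        """Sidecar annotation: name, hairpin_id, arm, role, variant_of, context_3p."""
        with open(path, "w") as fh:
            fh.write("name\thairpin_id\tarm\trole\tvariant_of\tcontext_3p\n")
            for s in self.species:
                fh.write(
                    f"{s.name}\t{s.hairpin_id}\t{s.arm}\t{s.role}\t"
                    f"{s.variant_of or ''}\t{s.context_3p}\n"
                )

    @classmethod
    def from_fasta_tsv(cls, fasta: str | Path, tsv: str | Path) -> "MirnaDictionary":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        species = []
        with open(tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                name = row["name"]
                if name not in seqs:
                    raise ValueError(f"TSV species {name!r} missing from FASTA")
                species.append(
                    MirnaSpecies(
                        name=name,
                        sequence=seqs[name],
                        hairpin_id=row["hairpin_id"],
                        arm=row["arm"],
                        role=row["role"],
                        variant_of=row.get("variant_of") or None,
                        context_3p=row.get("context_3p", ""),
                    )
                )
        return cls(species)

    def to_fasta_str(self) -> str:
        buf = io.StringIO()
        SeqIO.write(
            [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in self.species],
            buf,
            "fasta",
        )
        return buf.getvalue()


def isoform_sequence(sp: MirnaSpecies, length: int) -> str:
    """Sequence of the length isoform of a species.

    Shorter isoforms are 3'-truncations of the reference; longer ones are
    extended with templated nucleotides from the stored hairpin context.
    """
    if length < PREFIX_LEN:
        raise ValueError(f"isoform length {length} below the {PREFIX_LEN}-nt minimum")
    ref = sp.sequence
    if length <= len(ref):
        return ref[:length]
    extra = length - len(ref)
    if extra > len(sp.context_3p):
        raise ValueError(
            f"species {sp.name!r}: isoform length {length} exceeds reference plus "
            f"available 3' context ({len(ref)}+{len(sp.context_3p)} nt)"
        )
    return ref + sp.context_3p[:extra]
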