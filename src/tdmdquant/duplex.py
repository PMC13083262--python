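"""miRNA-target duplex architecture annotation.

Formalizes the pairing geometries that distinguish degradation triggers from
ordinary targets: pairing to the miRNA seed (guide nucleotides 2-8), an
internal loop over the guide's central region, extensive pairing to the
guide 3' region, and the lengths of target sequence flanking the site.
Architectures:

* ``seed_only`` - seed pairing with at most marginal 3' pairing;
* ``supplementary`` - limited 3' pairing (raises affinity, does not trigger
  degradation);
* ``tdmd_like`` - extensive 3' pairing reaching near the guide 3' end,
  bridged by an internal loop (the trigger geometry);
* ``full`` - contiguous complementarity with no internal loop;
* ``no_site`` - no seed match in the target.

Conventions: coordinates are 1-based inclusive; the guide is written 5'->3'
and its nucleotide 1 is never paired (anchored inside AGO); pairing is
Watson-Crick-Franklin only unless ``wobble=True`` adds G:U pairs. Sequences
may be RNA or DNA (T and U are equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

SEED_START, SEED_END = 2, 8  # guide positions of the seed
_ALPHABET = set("ACGU")

_WCF = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = _WCF | {("G", "U"), ("U", "G")}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _normalize(seq: str, label: str) -> str:
    s = seq.upper().replace("T", "U")
    if not s or set(s) - _ALPHABET:
        raise ValueError(f"{label} contains characters outside the RNA/DNA alphabet")
    return s


def _pairs(a: str, b: str, wobble: bool) -> bool:
    return (a, b) in (_WOBBLE if wobble else _WCF)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def find_seed_site(guide: str, target: str) -> list[int]:
    """All target positions (1-based start) matching the guide seed.

    A site is a contiguous Watson-Crick-Franklin match of the reverse
    complement of guide nucleotides 2-8 in the target. Overlapping
    occurrences are all reported.
    """
    g = _normalize(guide, "guide")
    t = _normalize(target, "target")
    if len(g) < 14:
        raise ValueError("guide must be at least 14 nt")
    probe = reverse_complement(g[SEED_START - 1 : SEED_END])
    hits = []
    start = 0
    while True:
        i = t.find(probe, start)
        if i < 0:
            return hits
        hits.append(i + 1)
        start = i + 1


@dataclass(frozen=True)
class ThreePrimeRegister:
    """Best 3'-pairing register downstream of a seed site.

    ``length`` contiguous pairs between guide positions
    [guide_start, guide_end] and target positions [target_start, target_end]
    (target coordinates decrease 3'->5' along the guide); ``loop_guide`` /
    ``loop_target`` are the unpaired nucleotides bridging seed and 3' block
    on each strand. length 0 means no 3' pairing.
    """

    loop_guide: int
    loop_target: int
    length: int
    guide_start: int | None
    guide_end: int | None
    target_start: int | None
    target_end: int | None


def align_three_prime(
    guide: str,
    target: str,
    seed_site: int,
    max_loop_guide: int = 8,
    max_loop_target: int = 16,
    wobble: bool = False,
) -> ThreePrimeRegister:
    """Best contiguous 3' duplex register for a given seed site.

    Enumerates all loop combinations (0..max_loop_guide unpaired guide nt
    after position 8, 0..max_loop_target unpaired target nt 5' of the seed
    match) and returns the register with the most contiguous pairs between
    guide nt >= 9 and the target; ties prefer the smaller target loop, then
    the smaller guide loop.
    """
    g = _normalize(guide, "guide")
    t = _normalize(target, "target")
    if not (1 <= seed_site <= len(t) - (SEED_END - SEED_START)):
        raise ValueError("seed_site out of range")
    best = ThreePrimeRegister(0, 0, 0, None, None, None, None)
    for lt in range(max_loop_target + 1):
        for lg in range(max_loop_guide + 1):
            gi = SEED_END + 1 + lg  # first paired guide position
            ti = seed_site - 1 - lt  # first paired target position
            n = 0
            while gi + n <= len(g) and ti - n >= 1 and _pairs(g[gi + n - 1], t[ti - n - 1], wobble):
                n += 1
            if n > best.length:
                best = ThreePrimeRegister(lg, lt, n, gi, gi + n - 1, ti, ti - n + 1)
    return best


ARCHITECTURES = ("no_site", "seed_only", "supplementary", "tdmd_like", "full")


@dataclass(frozen=True)
class DuplexAnnotation:
    """Full pairing annotation of one guide-target duplex."""

    guide: str
    target: str
    guide_len: int
    seed_site: int | None  # 1-based target start of the seed match
    seed_span: tuple[int, int] | None  # guide positions paired in the seed
    three_prime: ThreePrimeRegister | None
    loop_guide: int
    loop_target: int
    flank5_len: int
    flank3_len: int
    total_paired: int
    architecture: str

    @property
    def three_prime_len(self) -> int:
        return self.three_prime.length if self.three_prime else 0


def classify_architecture(
    ann: DuplexAnnotation,
    tdmd_min_three_prime: int = 8,
    tdmd_end_distance: int = 3,
    seed_only_max_three_prime: int = 2,
    full_max_unpaired: int = 2,
) -> str:
    """Assign an architecture class to an annotated duplex.

    * ``full``: no internal loop and total pairing within
      ``full_max_unpaired`` of the guide length;
    * ``tdmd_like``: >= ``tdmd_min_three_prime`` contiguous 3' pairs reaching
      within ``tdmd_end_distance`` nt of the guide 3' end, with a non-empty
      internal loop on at least one strand;
    * ``seed_only``: at most ``seed_only_max_three_prime`` 3' pairs;
    * ``supplementary``: everything else (moderate 3' pairing, or 3' pairing
      that stops short of the guide 3' end).

    The numeric thresholds are operational defaults, not measured constants;
    they are exposed as parameters.
    """
    if ann.seed_site is None:
        return "no_site"
    n3 = ann.three_prime_len
    no_loop = ann.loop_guide == 0 and ann.loop_target == 0 and n3 > 0
    if no_loop and ann.total_paired >= ann.guide_len - full_max_unpaired:
        return "full"
    reaches_end = (
        n3 > 0 and ann.three_prime.guide_end >= ann.guide_len - tdmd_end_distance
    )
    if (
        n3 >= tdmd_min_three_prime
        and reaches_end
        and (ann.loop_guide + ann.loop_target >= 1)
    ):
        return "tdmd_like"
    if n3 <= seed_only_max_three_prime:
        return "seed_only"
    return "supplementary"


def annotate_duplex(
    guide: str,
    target: str,
    max_loop_guide: int = 8,
    max_loop_target: int = 16,
    wobble: bool = False,
    **class_kwargs,
) -> DuplexAnnotation:
    """Annotate seed match, 3' pairing, loops, flanks and architecture.

    When the target holds several seed sites, the one yielding the most
    total pairing is annotated (leftmost on ties). Flank lengths run from
    the outermost paired target nucleotide to each target end (5' flank is
    upstream of the 3'-pairing block, 3' flank downstream of the seed).
    """
    g = _normalize(guide, "guide")
    t = _normalize(target, "target")
    sites = find_seed_site(g, t)
    if not sites:
        return DuplexAnnotation(
            g, t, len(g), None, None, None, 0, 0, 0, 0, 0, "no_site"
        )
    best_site, best_reg, best_total = None, None, -1
    for s in sites:
        reg = align_three_prime(g, t, s, max_loop_guide, max_loop_target, wobble)
        total = (SEED_END - SEED_START + 1) + reg.length
        if total > best_total:
            best_site, best_reg, best_total = s, reg, total
    seed_hi = best_site + (SEED_END - SEED_START)  # last target nt of the seed match
    max_paired_t = seed_hi
    min_paired_t = best_reg.target_end if best_reg.length else best_site
    ann = DuplexAnnotation(
        guide=g,
        target=t,
        guide_len=len(g),
        seed_site=best_site,
        seed_span=(SEED_START, SEED_END),
        three_prime=best_reg,
        loop_guide=best_reg.loop_guide if best_reg.length else 0,
        loop_target=best_reg.loop_target if best_reg.length else 0,
        flank5_len=min_paired_t - 1,
        flank3_len=len(t) - max_paired_t,
        total_paired=best_total,
        architecture="",
    )
    arch = classify_architecture(ann, **class_kwargs)
    return DuplexAnnotation(**{**ann.__dict__, "architecture": arch})


def annotation_to_dict(ann: DuplexAnnotation) -> dict:
    """JSON-serializable summary of an annotation."""
    return {
        "guide_len": ann.guide_len,
        "seed_site": ann.seed_site,
        "seed_span": list(ann.seed_span) if ann.seed_span else None,
        "three_prime_len": ann.three_prime_len,
        "three_prime_guide_span": (
            [ann.three_prime.guide_start, ann.three_prime.guide_end]
            if ann.three_prime and ann.three_prime.length
            else None
        ),
        "loop_guide": ann.loop_guide,
        "loop_target": ann.loop_target,
        "flank5_len": ann.flank5_len,
        "flank3_len": ann.flank3_len,
        "total_paired": ann.total_paired,
        "architecture": ann.architecture,
    }
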