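"""Synthetic-data generators with embedded ground truth.

Every input the analysis needs can be generated here: miRNA dictionaries
(with deliberate 13-nt prefix collisions to exercise collapsing), per-species
x per-length negative-binomial count tables for a 3-knockout vs 3-control
design, FASTQ reads that invert the mapping pipeline, co-IP gel band
intensities and quadratic-isotherm titration series. Each generator is
deterministic for a fixed seed, and the ground truth travels with the
artifact (as an attribute in memory, as a JSON sidecar on disk) so recovery
tests can compare estimates against it.

The count model: the expected count of species i at length l in sample j is

    sf_j * base_i * profile_{i,l} * 2^(KO_j * (lfc_tdmd_i + lfc_short_i * [l < 19]))

i.e. a library-size factor, a per-species abundance at its modal length
profile, a knockout effect shared by all isoforms of a TDMD-sensitive miRNA,
and an extra knockout effect confined to isoforms shorter than 19 nt
(extensively trimmed species whose 3' end can no longer occupy the PAZ
pocket). Counts are negative-binomial with per-species dispersion alpha
(variance mu + alpha*mu^2), drawn as gamma-Poisson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tdmdquant.binding import TitrationCurve, eval_quadratic
from tdmdquant.dictionary import (
    PREFIX_LEN,
    MirnaDictionary,
    MirnaSpecies,
    isoform_sequence,
)
from tdmdquant.pipeline import LENGTH_MAX, LENGTH_MIN, IsoformCountTable

_NT = np.array(list("ACGT"))

KO = "KO"
CONTROL = "control"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


# --------------------------------------------------------------------------- #
# dictionary generator
# --------------------------------------------------------------------------- #
def make_mirna_dictionary(
    n_hairpins: int, prefix_collision_rate: float = 0.0, seed: int = 0
) -> MirnaDictionary:
    """Generate a dictionary of ``n_hairpins`` hairpins (mature + passenger each).

    ``prefix_collision_rate`` is the fraction of mature species placed into
    deliberate shared-13-nt-prefix groups (to exercise collapsing): the
    requested number round(n * rate) of matures is arranged into groups of
    two (one group of three if odd) that share a prefix but differ later in
    the sequence. All other prefixes, and all passenger prefixes, are
    distinct. Deterministic for a fixed seed.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    if not (0 <= prefix_collision_rate < 1):
        raise ValueError("prefix_collision_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    used_prefixes: set[str] = set()

    def fresh_seq(length: int) -> str:
        while True:
            s = _random_seq(rng, length)
            if s[:PREFIX_LEN] not in used_prefixes:
                used_prefixes.add(s[:PREFIX_LEN])
                return s

    species: list[MirnaSpecies] = []
    mature_seqs: list[str] = []
    for h in range(n_hairpins):
        hp = f"hp{h:04d}"
        mat = fresh_seq(22)
        pas = fresh_seq(22)
        mature_seqs.append(mat)
        species.append(
            MirnaSpecies(
                name=f"mir{h:04d}-5p",
                sequence=mat,
                hairpin_id=hp,
                arm="5p",
                role="mature",
                context_3p=_random_seq(rng, 12),
            )
        )
        species.append(
            MirnaSpecies(
                name=f"mir{h:04d}-3p",
                sequence=pas,
                hairpin_id=hp,
                arm="3p",
                role="passenger",
                context_3p=_random_seq(rng, 12),
            )
        )

    n_collide = round(n_hairpins * prefix_collision_rate)
    if n_collide == 1:
        n_collide = 2  # a singleton cannot share a prefix
    if n_collide > 0:
        chosen = rng.choice(n_hairpins, size=n_collide, replace=False)
        groups = [chosen[i : i + 2] for i in range(0, n_collide - (n_collide % 2), 2)]
        if n_collide % 2:  # fold the odd one into the last group
            groups[-1] = np.concatenate([groups[-1], chosen[-1:]])
        rebuilt = {}
        for grp in groups:
            leader = int(grp[0])
            prefix = mature_seqs[leader][:PREFIX_LEN]
            for h in map(int, grp[1:]):
                old = mature_seqs[h]
                used_prefixes.discard(old[:PREFIX_LEN])
                new_seq = prefix + old[PREFIX_LEN:]
                rebuilt[h] = new_seq
        for h, new_seq in rebuilt.items():
            old_sp = next(s for s in species if s.name == f"mir{h:04d}-5p")
            species[species.index(old_sp)] = MirnaSpecies(
                name=old_sp.name,
                sequence=new_seq,
                hairpin_id=old_sp.hairpin_id,
                arm=old_sp.arm,
                role=old_sp.role,
                context_3p=old_sp.context_3p,
            )
    return MirnaDictionary(species)


# --------------------------------------------------------------------------- #
# count simulation
# --------------------------------------------------------------------------- #
def default_length_profile(
    modal_length: int = 22, sd: float = 1.2, floor: float = 0.005
) -> np.ndarray:
    """Distribution over lengths 13-31: discretized normal around the modal
    length plus a uniform floor so trimmed/tailed isoforms are represented."""
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    w = np.exp(-0.5 * ((lengths - modal_length) / sd) ** 2) + floor
    return w / w.sum()


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated 3-KO vs 3-control isoform count table."""

    design: dict[str, str]  # sample -> "KO" | "control"
    base_abundance: dict[str, float]  # expected count at the modal length scale
    length_profile: dict[str, list[float]]  # per species, over lengths 13..31
    lfc_tdmd: dict[str, float]  # true log2 KO/control, all isoforms
    lfc_short: dict[str, float]  # extra log2 KO/control, lengths < short_threshold
    dispersion: dict[str, float]  # NB alpha per species
    size_factor_truth: dict[str, float]  # per-sample scale
    short_threshold: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        groups = set(self.design.values())
        if groups != {KO, CONTROL}:
            raise ValueError(f"design groups must be exactly {{{KO!r}, {CONTROL!r}}}")
        for name, prof in self.length_profile.items():
            prof = np.asarray(prof, dtype=float)
            if len(prof) != LENGTH_MAX - LENGTH_MIN + 1:
                raise ValueError(f"{name}: length profile must cover 13..31")
            if not np.isclose(prof.sum(), 1.0):
                raise ValueError(f"{name}: length profile must sum to 1")
        if any(d <= 0 for d in self.dispersion.values()):
            raise ValueError("dispersions must be > 0")
        if any(s <= 0 for s in self.size_factor_truth.values()):
            raise ValueError("true size factors must be > 0")

    @property
    def samples(self) -> list[str]:
        return list(self.design)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_design() -> dict[str, str]:
    """The study design: three knockout and three control libraries."""
    return {f"ko_{i}": KO for i in (1, 2, 3)} | {f"ctrl_{i}": CONTROL for i in (1, 2, 3)}


def make_simulation_truth(
    dictionary: MirnaDictionary,
    seed: int = 0,
    frac_sensitive: float = 0.1,
    lfc_sensitive: float = 1.0,
    lfc_short: float = 0.5,
    base_range: tuple[float, float] = (50.0, 5000.0),
    passenger_fraction: float = 0.05,
    dispersion: float = 0.05,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    short_threshold: int = 19,
    design: Mapping[str, str] | None = None,
) -> SimulationTruth:
    """Default ground truth for a dictionary.

    A fraction of mature species are TDMD-sensitive (true log2 KO/control
    effect ``lfc_sensitive`` on all isoforms); every mature species carries
    the length-dependent short-isoform effect ``lfc_short`` on isoforms below
    ``short_threshold`` nt; passenger strands carry no effect (production is
    unchanged) and are expressed at ``passenger_fraction`` of a typical
    mature abundance. Base abundances are log-uniform over ``base_range``.
    """
    rng = np.random.default_rng(seed)
    design = dict(design) if design is not None else default_design()
    profile = default_length_profile().tolist()

    matures = dictionary.matures()
    n_sens = round(len(matures) * frac_sensitive)
    sensitive = set(
        rng.choice([m.name for m in matures], size=n_sens, replace=False).tolist()
    )

    base, lfc_t, lfc_s, disp, profiles = {}, {}, {}, {}, {}
    for sp in dictionary:
        if sp.role == "mature":
            base[sp.name] = float(
                np.exp(rng.uniform(np.log(base_range[0]), np.log(base_range[1])))
            )
            lfc_t[sp.name] = lfc_sensitive if sp.name in sensitive else 0.0
            lfc_s[sp.name] = lfc_short
        else:
            base[sp.name] = float(
                passenger_fraction
                * np.exp(rng.uniform(np.log(base_range[0]), np.log(base_range[1])))
            )
            lfc_t[sp.name] = 0.0
            lfc_s[sp.name] = 0.0
        disp[sp.name] = dispersion
        profiles[sp.name] = profile
    sf = {
        s: float(np.exp(rng.uniform(np.log(size_factor_range[0]), np.log(size_factor_range[1]))))
        for s in design
    }
    return SimulationTruth(
        design=design,
        base_abundance=base,
        length_profile=profiles,
        lfc_tdmd=lfc_t,
        lfc_short=lfc_s,
        dispersion=disp,
        size_factor_truth=sf,
        short_threshold=short_threshold,
        seed=int(seed),
    )


def expected_counts(truth: SimulationTruth) -> pd.DataFrame:
    """Expected count matrix implied by the truth (rows (species, length))."""
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    rows = []
    index = []
    for name, base in truth.base_abundance.items():
        prof = np.asarray(truth.length_profile[name])
        for li, length in enumerate(lengths):
            mu_row = []
            for sample in truth.samples:
                g = 1.0 if truth.design[sample] == KO else 0.0
                lfc = truth.lfc_tdmd[name] + (
                    truth.lfc_short[name] if length < truth.short_threshold else 0.0
                )
                mu_row.append(
                    truth.size_factor_truth[sample] * base * prof[li] * 2.0 ** (g * lfc)
                )
            rows.append(mu_row)
            index.append((name, int(length)))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["mirna", "length"]),
        columns=truth.samples,
    )


def simulate_isoform_counts(
    dictionary: MirnaDictionary, truth: SimulationTruth
) -> IsoformCountTable:
    """Draw a negative-binomial isoform count table under ``truth``.

    Counts for species i, length l, sample j have mean
    ``sf_j * base_i * profile_{i,l} * 2^(KO_j * (lfc_tdmd_i + lfc_short_{i,l}))``
    and NB dispersion ``alpha_i`` (gamma-Poisson; Poisson when alpha ~ 0).
    The returned table carries ``truth`` as an attribute for recovery tests.
    """
    samples = truth.samples
    n_ko = sum(1 for g in truth.design.values() if g == KO)
    if len(samples) != 6 or n_ko != 3:
        raise ValueError("design must have 6 samples, 3 KO and 3 control")
    for name in truth.base_abundance:
        if name not in dictionary:
            raise ValueError(f"truth references unknown species {name!r}")
    rng = np.random.default_rng(truth.seed)
    mu = expected_counts(truth)
    counts = np.empty(mu.shape, dtype=int)
    for i, name in enumerate(mu.index.get_level_values("mirna")):
        alpha = truth.dispersion[name]
        row_mu = mu.iloc[i].to_numpy()
        if alpha < 1e-12:
            counts[i] = rng.poisson(row_mu)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * row_mu)
            counts[i] = rng.poisson(lam)
    table = IsoformCountTable(pd.DataFrame(counts, index=mu.index, columns=samples))
    table.truth = truth
    return table


# --------------------------------------------------------------------------- #
# FASTQ generation (inverse of the mapping pipeline)
# --------------------------------------------------------------------------- #
def _qual_string(rng: np.random.Generator, n: int, good: bool) -> str:
    # good reads: per-base Q32-40; bad reads: Q <= 30 across all bases
    if good:
        q = rng.integers(32, 41, size=n)
    else:
        q = np.full(n, int(rng.integers(2, 31)))
    return "".join(chr(int(x) + 33) for x in q)


def counts_to_fastq(
    table: IsoformCountTable,
    dictionary: MirnaDictionary,
    adapter: str,
    out_dir: str | Path,
    contamination_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 60,
) -> dict[str, Path]:
    """Write one FASTQ per sample in which every count unit becomes one read.

    A read is the isoform sequence (the species truncated or 3'-extended to
    the recorded length), the adapter, then random filler up to
    ``read_length`` (longer inserts keep the full adapter and exceed it).
    ``contamination_rate`` adds Poisson(rate * n_true) extra reads per
    sample, half unmappable (random insert) and half low-quality. A truth
    sidecar JSON (counts, and the simulation truth when the table carries
    one) is written alongside. Returns {sample: fastq path}.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    if contamination_rate < 0:
        raise ValueError("contamination_rate must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    adapter = adapter.upper().replace("U", "T")

    paths: dict[str, Path] = {}
    for sample in table.samples:
        reads: list[tuple[str, str]] = []
        col = table.counts[sample]
        for (name, length), n in col.items():
            if n == 0:
                continue
            iso = isoform_sequence(dictionary[name], int(length))
            for _ in range(int(n)):
                core = iso + adapter
                filler = _random_seq(rng, max(read_length - len(core), 0))
                seq = core + filler
                reads.append((seq, _qual_string(rng, len(seq), good=True)))
        n_contam = int(rng.poisson(contamination_rate * len(reads)))
        for k in range(n_contam):
            insert = _random_seq(rng, int(rng.integers(20, 36)))
            core = insert + adapter
            filler = _random_seq(rng, max(read_length - len(core), 0))
            seq = core + filler
            good = k % 2 == 0  # half unmappable-but-clean, half low-quality
            reads.append((seq, _qual_string(rng, len(seq), good=good)))
        order = rng.permutation(len(reads))
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for ridx, i in enumerate(order):
                seq, qual = reads[i]
                fh.write(f"@{sample}_read{ridx}\n{seq}\n+\n{qual}\n")
        paths[sample] = path

    sidecar = {"counts": table.to_long().to_dict(orient="records")}
    if hasattr(table, "truth"):
        sidecar["truth"] = asdict(table.truth)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return paths


# --------------------------------------------------------------------------- #
# gel and titration generators
# --------------------------------------------------------------------------- #
@dataclass
class GelTruth:
    """Ground truth for a simulated co-IP gel.

    ``lanes`` is an ordered list of (bait_label, bait_concentration_nM,
    target_label); ``true_fraction_bound`` gives the underlying pull-down
    fraction per lane (the T6B lane of each target is 1 by definition, the
    0 nM lane 0). Band intensity is background + gain * fraction * noise,
    with log-normal multiplicative noise of coefficient of variation
    ``noise_cv``.
    """

    lanes: list[tuple[str, float, str]]
    true_fraction_bound: list[float]
    background_level: float = 50.0
    noise_cv: float = 0.0
    gain: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lanes) != len(self.true_fraction_bound):
            raise ValueError("lanes and true_fraction_bound differ in length")
        if any(not (0 <= f <= 1) for f in self.true_fraction_bound):
            raise ValueError("true fractions must lie in [0, 1]")
        targets = {t for _, _, t in self.lanes}
        for t in targets:
            baits = [b for b, _, tt in self.lanes if tt == t]
            if baits.count("T6B") != 1:
                raise ValueError(f"target {t!r}: need exactly one T6B lane")
            if baits.count("none") != 1:
                raise ValueError(f"target {t!r}: need exactly one 0 nM lane")


def make_gel_truth(
    target_curves: Mapping[str, Mapping[float, float]],
    background_level: float = 50.0,
    noise_cv: float = 0.0,
    gain: float = 1000.0,
    seed: int = 0,
) -> GelTruth:
    """Build a GelTruth from {target: {bait conc (nM): true fraction bound}},
    adding the mandatory 0 nM (fraction 0) and T6B (fraction 1) control lanes."""
    lanes: list[tuple[str, float, str]] = []
    fracs: list[float] = []
    for target, curve in target_curves.items():
        lanes.append(("none", 0.0, target))
        fracs.append(0.0)
        lanes.append(("T6B", float("nan"), target))
        fracs.append(1.0)
        for conc, frac in curve.items():
            lanes.append(("ZSWIM8", float(conc), target))
            fracs.append(float(frac))
    return GelTruth(lanes, fracs, background_level, noise_cv, gain, seed)


def simulate_coip_gel(truth: GelTruth, n_blanks: int = 4) -> pd.DataFrame:
    """Simulate phosphorimager band intensities for a co-IP gel.

    Returns a lane table (target, bait, conc_nM, intensity) including
    ``n_blanks`` blank-region rectangles for background estimation, directly
    consumable by :func:`tdmdquant.binding.quantify_gel`.
    """
    rng = np.random.default_rng(truth.seed)
    sigma = float(np.sqrt(np.log1p(truth.noise_cv**2)))

    def noise() -> float:
        if sigma == 0:
            return 1.0
        return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))

    rows = []
    for (bait, conc, target), frac in zip(truth.lanes, truth.true_fraction_bound):
        intensity = truth.background_level + truth.gain * frac * noise()
        rows.append(
            {"target": target, "bait": bait, "conc_nM": conc, "intensity": intensity}
        )
    for _ in range(n_blanks):
        rows.append(
            {
                "target": "blank",
                "bait": "blank",
                "conc_nM": np.nan,
                "intensity": truth.background_level * noise(),
            }
        )
    return pd.DataFrame(rows)


def simulate_titration(
    stock_truth: float,
    dilution_factors: Sequence[float],
    target_total: float,
    kd_truth: float,
    fmax_truth: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Noisy titration series under the quadratic (ligand-depletion) isotherm.

    Gaussian noise of standard deviation ``noise_sd`` is added to the
    fraction bound and truncated to [0, 1].
    """
    if stock_truth <= 0 or target_total <= 0 or kd_truth <= 0:
        raise ValueError("concentrations must be positive")
    if not (0 < fmax_truth <= 1):
        raise ValueError("fmax_truth must lie in (0, 1]")
    df = np.asarray(dilution_factors, dtype=float)
    f = eval_quadratic(stock_truth, df, target_total, kd_truth, fmax_truth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, size=f.shape), 0.0, 1.0)
    return TitrationCurve(df, f, target_total)
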