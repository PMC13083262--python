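"""Differential stability of miRNAs and their length isoforms after ZSWIM8 loss.

The workflow mirrors a DESeq2-style two-group comparison but with a
transparent, self-contained estimator:

1. sum all length isoforms of each miRNA;
2. filter on expression (> 5 reads in >= 2 knockout libraries and >= 30 reads
   across all six libraries);
3. median-of-ratios size factors from the summed counts;
4. per-miRNA log2 fold change (normalized-mean ratio with a pseudocount),
   delta-method standard error under a method-of-moments negative-binomial
   dispersion, and a Wald p-value;
5. Benjamini-Hochberg adjustment;
6. three-way classification of potentially ZSWIM8-sensitive miRNAs
   (adjusted significance, separation from the passenger strand,
   external annotation), whose union is excluded from isoform-level analysis;
7. per-isoform fold changes normalized with the *summed* size factors,
   centered on the median 22-nt fold change;
8. a one-sided Wilcoxon signed-rank test for accumulation of <19-nt isoforms.

Fold changes are always knockout over control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tdmdquant.dictionary import MirnaDictionary
from tdmdquant.pipeline import CollapsedIndex, IsoformCountTable

KO = "KO"
CONTROL = "control"

#: default thresholds, as used throughout the analysis
MIN_READS_PER_KO_LIBRARY = 5  # strict: count must exceed this
MIN_KO_LIBRARIES = 2
MIN_TOTAL_READS = 30  # non-strict: total may equal this
ALPHA = 0.05
SHORT_THRESHOLD = 19
CENTERING_LENGTH = 22
DISPERSION_FLOOR = 1e-8


class NormalizationError(RuntimeError):
    """Size factors cannot be estimated (no miRNA positive in every sample)."""


class ContractError(ValueError):
    """Size factors of the wrong provenance were passed to the isoform level."""


def _split_design(design: Mapping[str, str]) -> tuple[list[str], list[str]]:
    groups = set(design.values())
    if groups != {KO, CONTROL}:
        raise ValueError(f"design must contain exactly the groups {KO!r} and {CONTROL!r}")
    ko = [s for s, g in design.items() if g == KO]
    ctrl = [s for s, g in design.items() if g == CONTROL]
    return ko, ctrl


# --------------------------------------------------------------------------- #
# summing, filtering, normalization
# --------------------------------------------------------------------------- #
def sum_isoforms(table: IsoformCountTable) -> pd.DataFrame:
    """Sum reads over all length isoforms of each miRNA (miRNA x sample)."""
    return table.counts.groupby(level="mirna", sort=True).sum()


def filter_expressed(summed: pd.DataFrame, design: Mapping[str, str]) -> pd.Index:
    """Expression filter: keep miRNAs with more than 5 reads in at least two
    knockout libraries and at least 30 reads across all six libraries."""
    ko, ctrl = _split_design(design)
    if len(ko) != 3 or len(ctrl) != 3:
        raise ValueError("expected 3 knockout and 3 control samples")
    enough_ko = (summed[ko] > MIN_READS_PER_KO_LIBRARY).sum(axis=1) >= MIN_KO_LIBRARIES
    enough_total = summed[ko + ctrl].sum(axis=1) >= MIN_TOTAL_READS
    return summed.index[enough_ko & enough_total]


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample scale factors plus the provenance of the counts they came
    from ("summed" for miRNA-level sums, required at the isoform level)."""

    factors: pd.Series
    provenance: str = "summed"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise NormalizationError("size factors must be positive")


def estimate_size_factors(
    summed: pd.DataFrame, provenance: str = "summed"
) -> SizeFactors:
    """Median-of-ratios size factors.

    Reference miRNAs are those with positive counts in every sample; the
    factor of sample j is the median over references of
    count_ij / geometric_mean_i(counts).
    """
    counts = summed.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no miRNA has positive counts in every sample")
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1, keepdims=True)
    # median taken in ratio space (for an even reference count, the midpoint
    # of the two central ratios, not of their logs)
    factors = np.median(np.exp(logc - log_geomean), axis=0)
    return SizeFactors(pd.Series(factors, index=summed.columns), provenance)


# --------------------------------------------------------------------------- #
# fold changes
# --------------------------------------------------------------------------- #
def estimate_fold_changes(
    summed: pd.DataFrame,
    design: Mapping[str, str],
    size_factors: SizeFactors | pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group negative-binomial fold-change estimates.

    Per miRNA: lfc = log2((mean normalized KO + pc) / (mean normalized
    control + pc)); the standard error comes from the delta method with a
    per-miRNA method-of-moments NB dispersion (floored at 1e-8, averaged over
    the two groups); the p-value is a two-sided Wald test with a Student-t
    reference on n_KO + n_control - 2 degrees of freedom, which keeps the
    test calibrated at the study's 3 + 3 sample size.

    Returns a frame with columns lfc, se, p.
    """
    sf = size_factors.factors if isinstance(size_factors, SizeFactors) else size_factors
    ko, ctrl = _split_design(design)
    norm = summed / sf
    m_ko = norm[ko].mean(axis=1)
    m_ctrl = norm[ctrl].mean(axis=1)
    if pseudocount == 0 and ((m_ko == 0) | (m_ctrl == 0)).any():
        raise ValueError("a group mean is zero and pseudocount is 0: lfc undefined")

    def group_var_of_mean(cols: list[str], mean: pd.Series, alpha: pd.Series) -> pd.Series:
        return (mean + alpha * mean**2) / len(cols)

    def mom_alpha(cols: list[str], mean: pd.Series) -> pd.Series:
        var = norm[cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / mean**2
        return a.replace([np.inf, -np.inf], np.nan).fillna(0.0)

    alpha = ((mom_alpha(ko, m_ko) + mom_alpha(ctrl, m_ctrl)) / 2).clip(lower=DISPERSION_FLOOR)
    lfc = np.log2(m_ko + pseudocount) - np.log2(m_ctrl + pseudocount)
    var_lfc = (
        group_var_of_mean(ko, m_ko, alpha) / (m_ko + pseudocount) ** 2
        + group_var_of_mean(ctrl, m_ctrl, alpha) / (m_ctrl + pseudocount) ** 2
    ) / np.log(2) ** 2
    se = np.sqrt(var_lfc)
    dof = len(ko) + len(ctrl) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2 * stats.t.sf(np.abs(z.fillna(0.0)), df=dof)
    p = np.where(se == 0, np.where(lfc == 0, 1.0, 0.0), p)
    return pd.DataFrame({"lfc": lfc, "se": se, "p": p}, index=summed.index)


def adjust_bh(p: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment (monotone)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    padj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(padj, index=p.index)
    return padj


# --------------------------------------------------------------------------- #
# sensitivity classification
# --------------------------------------------------------------------------- #
def passenger_map_from_dictionary(
    dictionary: MirnaDictionary, index: CollapsedIndex | None = None
) -> dict[str, list[str]]:
    """Map each mature miRNA (or collapsed entry) to its passenger strands.

    With a CollapsedIndex, keys and values are collapsed-entry names (a
    collapsed mature entry inherits the passengers of all its members);
    otherwise raw species names are used.
    """

    def key_of(name: str) -> str:
        if index is None:
            return name
        return index.collapsed_name_of(name) or name

    out: dict[str, list[str]] = {}
    for sp in dictionary.matures():
        k = key_of(sp.name)
        passengers = [key_of(p.name) for p in dictionary.passengers_of(sp.name)]
        out.setdefault(k, [])
        for p in passengers:
            if p not in out[k]:
                out[k].append(p)
    return out


def passenger_fold_changes(
    summed_all: pd.DataFrame,
    design: Mapping[str, str],
    size_factors: SizeFactors | pd.Series,
    passenger_map: Mapping[str, Sequence[str]],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Fold change and SE of each miRNA's (summed) passenger strands.

    Passenger counts are taken from the *unfiltered* summed table (passenger
    strands are often below the expression cutoff); for miRNAs with several
    passengers the passenger counts are summed before estimation. miRNAs
    whose passengers are absent from the counts get NaN with a warning.
    Returns columns passenger_lfc, passenger_se indexed like passenger_map.
    """
    rows = {}
    missing = []
    for mature, passengers in passenger_map.items():
        present = [p for p in passengers if p in summed_all.index]
        if not present:
            missing.append(mature)
            continue
        rows[mature] = summed_all.loc[present].sum(axis=0)
    if missing:
        warnings.warn(
            f"{len(missing)} miRNA(s) have no passenger counts; "
            "passenger separation undefined for them",
            stacklevel=2,
        )
    if rows:
        mat = pd.DataFrame(rows).T
        fc = estimate_fold_changes(mat, design, size_factors, pseudocount)
    else:
        fc = pd.DataFrame(columns=["lfc", "se"])
    out = pd.DataFrame(
        index=pd.Index(list(passenger_map), name="mirna"),
        columns=["passenger_lfc", "passenger_se"],
        dtype=float,
    )
    out.loc[fc.index, "passenger_lfc"] = fc["lfc"]
    out.loc[fc.index, "passenger_se"] = fc["se"]
    return out


def classify_potentially_sensitive(
    results: pd.DataFrame,
    passenger_stats: pd.DataFrame | None = None,
    external_list: Sequence[str] = (),
    alpha: float = ALPHA,
    directional: bool = True,
) -> pd.DataFrame:
    """Flag potentially ZSWIM8-sensitive miRNAs by three approaches.

    * ``potentially_sensitive_padj``: adjusted p < alpha and log2 fold
      change > 0;
    * ``potentially_sensitive_passenger``: the miRNA's fold change is
      separated from its passenger's beyond their respective standard errors
      (directionally, mature above passenger, by default; set
      ``directional=False`` for absolute separation);
    * ``potentially_sensitive_annotation``: membership in an external list of
      previously called sensitive miRNAs.

    ``results`` needs columns lfc, se, padj; ``passenger_stats`` columns
    passenger_lfc, passenger_se (NaN rows leave the passenger flag False).
    ``excluded`` is the union of the three flags and the significant set, and
    marks miRNAs removed from isoform-level analysis.
    """
    out = results.copy()
    out["significant_up"] = (out["padj"] < alpha) & (out["lfc"] > 0)
    out["potentially_sensitive_padj"] = out["significant_up"]
    if passenger_stats is not None:
        ps = passenger_stats.reindex(out.index)
        lo_mature = out["lfc"] - out["se"]
        hi_pass = ps["passenger_lfc"] + ps["passenger_se"]
        if directional:
            sep = lo_mature > hi_pass
        else:
            sep = (out["lfc"] - ps["passenger_lfc"]).abs() > (
                out["se"] + ps["passenger_se"]
            )
        out["potentially_sensitive_passenger"] = sep.fillna(False)
        out["passenger_lfc"] = ps["passenger_lfc"]
        out["passenger_se"] = ps["passenger_se"]
    else:
        out["potentially_sensitive_passenger"] = False
    out["potentially_sensitive_annotation"] = out.index.isin(set(external_list))
    out["excluded"] = (
        out["significant_up"]
        | out["potentially_sensitive_padj"]
        | out["potentially_sensitive_passenger"]
        | out["potentially_sensitive_annotation"]
    )
    return out


# --------------------------------------------------------------------------- #
# isoform level
# --------------------------------------------------------------------------- #
def isoform_fold_changes(
    table: IsoformCountTable,
    size_factors: SizeFactors,
    design: Mapping[str, str],
    excluded: Sequence[str] = (),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-(miRNA, length) fold changes on size-factor-normalized counts.

    The size factors must come from the summed miRNA-level counts (their
    provenance is checked), not from per-isoform counts. Isoforms of excluded
    miRNAs are dropped. Returns a frame indexed by (mirna, length) with a
    column lfc.
    """
    if not isinstance(size_factors, SizeFactors) or size_factors.provenance != "summed":
        raise ContractError("isoform analysis requires size factors of provenance 'summed'")
    counts = table.counts
    if len(excluded):
        keep = ~counts.index.get_level_values("mirna").isin(set(excluded))
        counts = counts[keep]
    fc = estimate_fold_changes(counts, design, size_factors, pseudocount)
    return fc[["lfc"]]


def center_on_22nt(iso: pd.DataFrame) -> pd.DataFrame:
    """Subtract the median 22-nt log2 fold change from all isoform fold changes.

    Centers the 22-nt isoform distribution at zero, the behavior expected of
    species insensitive to ZSWIM8 loss. Requires at least one finite 22-nt
    fold change.
    """
    lengths = iso.index.get_level_values("length")
    ref = iso.loc[lengths == CENTERING_LENGTH, "lfc"].dropna()
    if ref.empty:
        raise ValueError(f"no {CENTERING_LENGTH}-nt isoforms: cannot center")
    med = float(ref.median())
    out = iso.copy()
    out["centered_lfc"] = out["lfc"] - med
    return out


class ShortIsoformResult(NamedTuple):
    statistic: float
    p: float
    effect_median: float  # median centered lfc of the short isoforms


def short_isoform_test(
    centered: pd.DataFrame, short_threshold: int = SHORT_THRESHOLD
) -> ShortIsoformResult:
    """One-sided Wilcoxon signed-rank test for accumulation of short isoforms.

    Tests whether the centered log2 fold changes of isoforms shorter than
    ``short_threshold`` nt are shifted above zero (short species accumulate
    after ZSWIM8 loss). Zeros are rank-split so an all-null input yields
    p ~ 0.5 rather than an error. Needs at least 5 short-isoform values.
    """
    lengths = centered.index.get_level_values("length")
    vals = centered.loc[lengths < short_threshold, "centered_lfc"].dropna().to_numpy()
    if len(vals) < 5:
        raise ValueError(
            f"only {len(vals)} isoforms shorter than {short_threshold} nt; need >= 5"
        )
    stat, p = stats.wilcoxon(vals, alternative="greater", zero_method="zsplit")
    return ShortIsoformResult(float(stat), float(p), float(np.median(vals)))


# --------------------------------------------------------------------------- #
# end-to-end convenience
# --------------------------------------------------------------------------- #
@dataclass
class StabilityResult:
    """Bundle of the full differential-stability analysis.

    ``per_mirna``: summed-level statistics, flags and exclusion status;
    ``per_isoform``: isoform fold changes with centered values (excluded
    miRNAs removed); ``short_test``: the <19-nt accumulation test (None when
    too few short isoforms); ``size_factors``: the summed-count size factors.
    """

    per_mirna: pd.DataFrame
    per_isoform: pd.DataFrame
    short_test: ShortIsoformResult | None
    size_factors: SizeFactors


def analyze(
    table: IsoformCountTable,
    design: Mapping[str, str],
    passenger_map: Mapping[str, Sequence[str]] | None = None,
    external_list: Sequence[str] = (),
    alpha: float = ALPHA,
    pseudocount: float = 0.5,
    short_threshold: int = SHORT_THRESHOLD,
    directional: bool = True,
) -> StabilityResult:
    """Run the complete summed + isoform-level analysis on a count table."""
    summed_all = sum_isoforms(table)
    retained = filter_expressed(summed_all, design)
    summed = summed_all.loc[retained]
    sf = estimate_size_factors(summed)
    res = estimate_fold_changes(summed, design, sf, pseudocount)
    res["padj"] = adjust_bh(res["p"])
    passenger_stats = None
    if passenger_map is not None:
        pm = {m: ps for m, ps in passenger_map.items() if m in res.index}
        passenger_stats = passenger_fold_changes(summed_all, design, sf, pm, pseudocount)
    res = classify_potentially_sensitive(
        res, passenger_stats, external_list, alpha, directional
    )
    res = res.rename(columns={"lfc": "summed_lfc", "se": "summed_se"})
    excluded = res.index[res["excluded"]]
    iso_table = IsoformCountTable(
        table.counts[table.counts.index.get_level_values("mirna").isin(retained)],
        table.counters.copy(),
    )
    iso = isoform_fold_changes(iso_table, sf, design, excluded, pseudocount)
    iso = center_on_22nt(iso)
    try:
        st = short_isoform_test(iso, short_threshold)
    except ValueError:
        st = None
    return StabilityResult(res, iso, st, sf)
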