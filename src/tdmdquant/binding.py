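"""Binding-assay quantification.

Covers the three readouts used to characterize ZSWIM8 recognition of
AGO-miRNA-trigger complexes:

* active-RISC titration against a fixed radiolabelled target, modelled by the
  ligand-depletion ("quadratic") isotherm and fit under constraints
  (F_max in (0,1], K_D in log space, gridded starts);
* co-IP gel-band quantification: blank-rectangle background subtraction,
  0 nM (no-bait) subtraction, normalization to the T6B lane, trigger vs
  seed-only fold enrichment with censoring, and log-linear interpolation of
  the bait concentration needed to reach a given pull-down level;
* single-site (hyperbolic) fits for filter-binding / biolayer-style dilution
  series, with the two-membrane fraction-bound convention.

Concentrations are in nM throughout unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """A nonlinear fit failed or the data are unidentifiable."""


class ControlError(ValueError):
    """A required control lane (0 nM or T6B) is missing."""


# --------------------------------------------------------------------------- #
# quadratic (ligand-depletion) isotherm
# --------------------------------------------------------------------------- #
def eval_quadratic(
    stock: float,
    DF: float | np.ndarray,
    target_T: float,
    K_D: float,
    F_max: float,
):
    """Fraction of target bound under the ligand-depletion binding isotherm.

    F_bound = ((DF*stock + target_T + K_D)
               - sqrt((DF*stock + target_T + K_D)^2 - 4*DF*stock*target_T))
              / (2*target_T) * F_max

    where ``DF*stock`` is the diluted concentration of active complex,
    ``target_T`` the total target concentration and ``K_D`` the dissociation
    constant. Evaluated in the algebraically equivalent form
    ``2*DF*stock / (b + sqrt(b^2 - 4*DF*stock*target_T)) * F_max`` which is
    stable when the discriminant approaches zero (stoichiometric limit).
    """
    DF = np.asarray(DF, dtype=float)
    if stock <= 0 or target_T <= 0 or K_D <= 0:
        raise ValueError("stock, target_T and K_D must be positive")
    if not (0 < F_max <= 1):
        raise ValueError("F_max must lie in (0, 1]")
    if np.any(DF <= 0):
        raise ValueError("dilution factors must be positive")
    a = DF * stock
    b = a + target_T + K_D
    disc = b * b - 4.0 * a * target_T
    disc = np.maximum(disc, 0.0)
    out = 2.0 * a / (b + np.sqrt(disc)) * F_max
    return out if out.ndim else float(out)


@dataclass
class TitrationCurve:
    """A dilution series of fraction-bound measurements plus optional fit.

    ``fitted`` holds {"stock", "K_D", "F_max"}; ``diagnostics`` the residual
    norm, convergence flag and the start grid that was searched.
    """

    dilution_factors: np.ndarray
    fraction_bound: np.ndarray
    target_total: float
    fitted: dict | None = None
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.dilution_factors.shape != self.fraction_bound.shape:
            raise ValueError("dilution_factors and fraction_bound differ in length")
        if np.any(self.dilution_factors <= 0):
            raise ValueError("dilution factors must be positive")
        d = np.diff(self.dilution_factors)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("dilution factors must be strictly monotone")
        if self.target_total <= 0:
            raise ValueError("target_total must be positive")
        if np.any(self.fraction_bound < -1e-9) or np.any(self.fraction_bound > 1 + 1e-9):
            raise ValueError("fraction bound must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"DF": self.dilution_factors, "fraction_bound": self.fraction_bound}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, target_total: float) -> "TitrationCurve":
        df = pd.read_csv(path)
        return cls(df["DF"].to_numpy(), df["fraction_bound"].to_numpy(), target_total)


#: start grid used by fit_quadratic_titration: multiples of the nominal stock,
#: absolute K_D values (nM) and F_max values.
QUAD_START_GRID = {
    "stock_mult": (0.1, 1.0, 10.0),
    "K_D": (1e-2, 1.0, 1e2),
    "F_max": (0.3, 0.6, 0.9),
}


def _nominal_stock(curve: TitrationCurve) -> float:
    # at half-plateau, DF*stock ~ target_T (+ K_D); use the DF closest to it
    f = curve.fraction_bound
    half = 0.5 * float(np.max(f))
    i = int(np.argmin(np.abs(f - half)))
    df_half = float(curve.dilution_factors[i])
    return max(curve.target_total / df_half, 1e-9)


def fit_quadratic_titration(
    curve: TitrationCurve, stock_nominal: float | None = None
) -> TitrationCurve:
    """Constrained least-squares fit of (stock, K_D, F_max) to a titration.

    Requires >= 4 points spanning at least one decade of dilution factor.
    K_D is optimized in log space; F_max is bounded to (0, 1); a grid of
    starting values (multiples of a nominal stock concentration, spread K_D
    and F_max values) is searched and the best-residual solution returned.
    Returns a new TitrationCurve with ``fitted`` and ``diagnostics`` set.
    """
    df, f = curve.dilution_factors, curve.fraction_bound
    if len(df) < 4:
        raise ValueError("need at least 4 titration points")
    if np.max(df) / np.min(df) < 10:
        raise ValueError("dilution factors must span at least one decade")
    if float(np.ptp(f)) < 1e-12 or float(np.max(f)) <= 0:
        raise FitError("flat response: parameters unidentifiable")
    nominal = stock_nominal if stock_nominal is not None else _nominal_stock(curve)

    def resid(p: np.ndarray) -> np.ndarray:
        stock, log_kd, fmax = p
        return eval_quadratic(stock, df, curve.target_total, np.exp(log_kd), fmax) - f

    bounds = ([1e-12, np.log(1e-8), 1e-9], [np.inf, np.log(1e8), 1.0])
    best = None
    n_converged = 0
    for sm in QUAD_START_GRID["stock_mult"]:
        for kd0 in QUAD_START_GRID["K_D"]:
            for fm0 in QUAD_START_GRID["F_max"]:
                x0 = np.array([sm * nominal, np.log(kd0), fm0])
                try:
                    res = least_squares(
                        resid, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
                    )
                except Exception:  # singular start; try the next one
                    continue
                if res.success:
                    n_converged += 1
                if best is None or res.cost < best.cost:
                    best = res
    if best is None or n_converged == 0:
        raise FitError("no start of the quadratic fit converged")
    stock, log_kd, fmax = best.x
    fitted = {"stock": float(stock), "K_D": float(np.exp(log_kd)), "F_max": float(fmax)}
    diagnostics = {
        "residual_norm": float(np.sqrt(2.0 * best.cost)),
        "converged": bool(best.success),
        "n_starts": int(np.prod([len(v) for v in QUAD_START_GRID.values()])),
        "n_converged": n_converged,
        "start_grid": QUAD_START_GRID,
        "stock_nominal": float(nominal),
    }
    return TitrationCurve(df, f, curve.target_total, fitted, diagnostics)


# --------------------------------------------------------------------------- #
# co-IP gel quantification
# --------------------------------------------------------------------------- #
def quantify_gel(lanes: pd.DataFrame, blank_mean: float | None = None) -> pd.DataFrame:
    """Background-subtract and normalize co-IP band intensities.

    ``lanes`` needs columns target, bait, conc_nM, intensity; bait is
    "ZSWIM8" (or any titrated bait label), "T6B", "none" (the 0 nM control)
    or "blank" (empty-region rectangles used for background estimation).

    For each target::

        value = (band - blank - (band_0nM - blank))
                / (band_T6B - blank - (band_0nM - blank))

    so the no-bait lane maps to 0 and the T6B lane to 1. Negative values are
    clipped at 0 with a warning. Returns a frame with columns
    target, conc_nM, normalized.
    """
    required = {"target", "bait", "intensity"}
    if not required.issubset(lanes.columns):
        raise ValueError(f"lane table must have columns {sorted(required)}")
    if blank_mean is None:
        blanks = lanes[lanes["bait"] == "blank"]
        if blanks.empty:
            raise ControlError("no blank rectangles and no blank_mean given")
        blank_mean = float(blanks["intensity"].mean())

    out_rows = []
    for target, grp in lanes[lanes["bait"] != "blank"].groupby("target", sort=False):
        zeros = grp[grp["bait"] == "none"]
        t6b = grp[grp["bait"] == "T6B"]
        if len(zeros) != 1:
            raise ControlError(f"target {target!r}: need exactly one 0 nM (no-bait) lane")
        if len(t6b) != 1:
            raise ControlError(f"target {target!r}: need exactly one T6B lane")
        zero_sig = float(zeros["intensity"].iloc[0]) - blank_mean
        denom = float(t6b["intensity"].iloc[0]) - blank_mean - zero_sig
        if denom <= 0:
            raise ControlError(f"target {target!r}: T6B signal not above the 0 nM lane")
        for _, lane in grp[~grp["bait"].isin(["none", "T6B"])].iterrows():
            val = (float(lane["intensity"]) - blank_mean - zero_sig) / denom
            if val < 0:
                warnings.warn(
                    f"target {target!r} at {lane['conc_nM']} nM: negative "
                    "normalized binding clipped to 0",
                    stacklevel=2,
                )
                val = 0.0
            out_rows.append(
                {"target": target, "conc_nM": float(lane["conc_nM"]), "normalized": val}
            )
    return pd.DataFrame(out_rows, columns=["target", "conc_nM", "normalized"])


@dataclass
class EnrichmentResult:
    """Per-concentration trigger:reference fold enrichment.

    ``folds`` has columns conc_nM, fold, censored; censored rows are lower
    bounds (the reference signal was at or below the floor, so the true fold
    is ">= fold"). ``max_fold`` is the largest fold in the series.
    """

    folds: pd.DataFrame
    max_fold: float
    max_censored: bool
    floor: float = 1e-3


def enrichment_ratio(
    trigger: pd.Series, reference: pd.Series, floor: float = 1e-3
) -> EnrichmentResult:
    """Fold enrichment of normalized trigger binding over a reference target.

    Both inputs are Series of normalized binding indexed by bait
    concentration. Reference values <= ``floor`` are replaced by the floor
    and the fold flagged censored, so "greater than N-fold" statements
    remain representable.
    """
    shared = trigger.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("no shared concentrations between trigger and reference")
    rows = []
    for c in sorted(shared):
        t, r = float(trigger[c]), float(reference[c])
        censored = r <= floor
        denom = max(r, floor)
        rows.append({"conc_nM": float(c), "fold": t / denom, "censored": censored})
    folds = pd.DataFrame(rows)
    i = int(folds["fold"].idxmax())
    return EnrichmentResult(
        folds, float(folds.loc[i, "fold"]), bool(folds.loc[i, "censored"]), floor
    )


def conc_at_pulldown(
    conc: Sequence[float], values: Sequence[float], level: float
) -> float:
    """Bait concentration at which binding reaches ``level``.

    Interpolates linearly in log concentration between the two observed
    points bracketing the level; a level observed exactly returns that
    concentration. Raises if the level is not bracketed by the data.
    """
    c = np.asarray(conc, dtype=float)
    v = np.asarray(values, dtype=float)
    if c.shape != v.shape or len(c) < 2:
        raise ValueError("need matching conc/value arrays with >= 2 points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(c)
    c, v = c[order], v[order]
    exact = np.isclose(v, level)
    if exact.any():
        return float(c[exact][0])
    for i in range(len(c) - 1):
        if (v[i] - level) * (v[i + 1] - level) < 0:
            lc = np.log(c[i]) + (level - v[i]) / (v[i + 1] - v[i]) * (
                np.log(c[i + 1]) - np.log(c[i])
            )
            return float(np.exp(lc))
    raise ValueError(f"pull-down level {level} is not bracketed by the data")


# --------------------------------------------------------------------------- #
# single-site fits and filter binding
# --------------------------------------------------------------------------- #
def fit_single_site(
    conc: Sequence[float], response: Sequence[float]
) -> tuple[float, float]:
    """Least-squares fit of R = R_max * c / (K_D + c); returns (K_D, R_max).

    Assumes the titrated species is in excess over the labelled tracer so
    free and total concentrations coincide. K_D is optimized in log space
    from a small start grid.
    """
    c = np.asarray(conc, dtype=float)
    r = np.asarray(response, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if float(np.ptp(r)) < 1e-12 or float(np.max(r)) <= 0:
        raise FitError("flat response: K_D unidentifiable")

    def resid(p: np.ndarray) -> np.ndarray:
        log_kd, rmax = p
        return rmax * c / (np.exp(log_kd) + c) - r

    rmax0 = float(np.max(r))
    best = None
    for kd0 in (float(np.min(c)), float(np.exp(np.mean(np.log(c)))), float(np.max(c))):
        for rm0 in (rmax0, 1.5 * rmax0):
            res = least_squares(
                resid,
                np.array([np.log(kd0), rm0]),
                bounds=([np.log(1e-10), 1e-12], [np.log(1e10), np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success:
        raise FitError("single-site fit did not converge")
    return float(np.exp(best.x[0])), float(best.x[1])


def filter_fraction_bound(
    nitrocellulose_signal: float,
    nylon_signal: float,
    nitrocellulose_background: float = 0.0,
    nylon_background: float = 0.0,
) -> float:
    """Fraction bound from a double-filter assay.

    Protein-bound RNA is retained on nitrocellulose, free RNA on the nylon
    membrane beneath; after per-membrane background subtraction the fraction
    bound is nitro / (nitro + nylon).
    """
    bound = max(nitrocellulose_signal - nitrocellulose_background, 0.0)
    free = max(nylon_signal - nylon_background, 0.0)
    if bound + free == 0:
        raise ValueError("both membrane signals are zero: fraction undefined")
    return bound / (bound + free)
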