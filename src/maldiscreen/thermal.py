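"""Thermal profiling analysis: melt-curve fitting, Tm shifts, hit rule, ITDR.

Model
-----
The fraction of a protein remaining soluble after heating to temperature T
follows the melt sigmoid

    f(T) = (1 - p) / (1 + exp(b - a / T)) + p

with slope parameter ``a`` (degC units), offset ``b`` (unitless) and lower
plateau ``p`` in [0, 0.5).  The melting temperature is the half-denaturation
point of the 0-to-1 span,

    Tm = a / (b - ln(0.5 / (0.5 - p)))        (Tm = a / b when p = 0).

The 1/T term uses the temperature unit of the input, so (a, b) are
unit-dependent while the recovered Tm is not (to within the fit tolerance).

A target engagement hit between two drug conditions requires, across all
replicates: both fits converged, a sign-consistent per-replicate Tm shift,
|mean dTm| above a threshold (default 2 degC) and SD(dTm) below 2 degC.

The isothermal dose-response (ITDR) counterpart fixes the temperature (56
degC in the validation experiments) and titrates the drug; the soluble
fraction follows the rising logistic b0 + (bmax - b0) / (1 + (EC50 / c)^h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError

DEFAULT_TEMPERATURES = (40.0, 44.0, 48.0, 52.0, 56.0, 60.0, 64.0, 68.0)

__all__ = [
    "DEFAULT_TEMPERATURES",
    "melt_model",
    "tm_from_params",
    "params_for_tm",
    "MeltFit",
    "fit_melting_curve",
    "fit_all_curves",
    "normalize_tpp",
    "TPPComparison",
    "compare_conditions",
    "delta_tm",
    "call_tpp_hits",
    "ITDRFit",
    "fit_itdr",
    "itdr_model",
]


def melt_model(T, a, b, p):
    """Soluble fraction at temperature T (same unit as used for fitting)."""
    T = np.asarray(T, dtype=float)
    return (1.0 - p) / (1.0 + np.exp(b - a / T)) + p


def tm_from_params(a: float, b: float, p: float) -> float:
    """Closed-form melting temperature; a/b exactly when p = 0."""
    denom = b - np.log(0.5 / (0.5 - p))
    if denom <= 0:
        return np.nan
    return a / denom


def params_for_tm(tm: float, b: float = 25.0, p: float = 0.02) -> tuple[float, float]:
    """Invert the Tm closed form: the (a, b) giving the requested Tm."""
    a = tm * (b - np.log(0.5 / (0.5 - p)))
    return a, b


@dataclass
class MeltFit:
    """Fitted melt-curve parameters for one protein/condition/replicate."""

    a: float = np.nan
    b: float = np.nan
    plateau: float = np.nan
    tm: float = np.nan
    r_squared: float = np.nan
    converged: bool = False


_B_STARTS = (8.0, 15.0, 25.0, 40.0, 60.0)


def fit_melting_curve(temperatures, rel_abundance) -> MeltFit:
    """Least-squares melt sigmoid fit with multi-start initialization.

    Requires >= 5 points.  Starts ``b`` on a fixed grid with ``a`` chosen so
    the initial Tm sits mid-range; bounds a > 0, b > 0, 0 <= p < 0.5.  Returns
    ``converged=False`` (no Tm) when no start converges or the data carry no
    melt transition (monotone increase, zero variance).
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(rel_abundance, dtype=float)
    if len(T) != len(y):
        raise ConfigError("temperatures and abundances differ in length")
    if len(T) < 5:
        raise ConfigError("need >= 5 temperature points to fit a melt curve")
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(y))):
        raise ConfigError("melt-curve values must be finite")
    if np.ptp(y) == 0 or np.all(np.diff(y) >= 0):
        return MeltFit(converged=False)

    t_mid = 0.5 * (T[0] + T[-1])
    best = None
    for b0 in _B_STARTS:
        p0 = [b0 * t_mid, b0, 0.02]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    melt_model, T, y, p0=p0,
                    bounds=([1e-6, 1e-6, 0.0], [np.inf, 500.0, 0.499]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((melt_model(T, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        return MeltFit(converged=False)
    ssr, (a, b, p) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    tm = tm_from_params(a, b, p)
    if not np.isfinite(tm) or tm <= 0:
        return MeltFit(a, b, p, np.nan, r2, False)
    return MeltFit(a, b, p, float(tm), r2, True)


def fit_all_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Fit every (protein, condition, replicate) trace in a long-format table.

    Expects columns protein, condition, replicate, temperature, rel_abundance;
    returns one row of fit parameters per trace.
    """
    rows = []
    for (prot, cond, rep), grp in table.groupby(["protein", "condition", "replicate"]):
        grp = grp.sort_values("temperature")
        fit = fit_melting_curve(grp["temperature"].values, grp["rel_abundance"].values)
        rows.append(
            {
                "protein": prot,
                "condition": cond,
                "replicate": rep,
                "a": fit.a,
                "b": fit.b,
                "plateau": fit.plateau,
                "tm": fit.tm,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def normalize_tpp(
    table: pd.DataFrame,
    reference_condition: str | None = None,
    r2_min: float = 0.8,
    plateau_max: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-based joint normalization of a relative-abundance table.

    Each trace is first scaled to 1 at its lowest temperature (traces missing
    that value are dropped with a count in the factors frame attrs).  Curves
    whose preliminary fit has R^2 > ``r2_min`` and plateau < ``plateau_max``
    form the normalization set; the melt sigmoid fitted to the reference
    condition's per-temperature medians defines the target curve, and each
    (condition, replicate) sample's medians are mapped onto it by
    per-temperature correction factors applied to all of that sample's curves.

    Returns ``(normalized table, factors)`` where factors has one row per
    (condition, replicate, temperature).
    """
    df = table.copy()
    dropped = 0
    pieces = []
    for key, grp in df.groupby(["protein", "condition", "replicate"]):
        grp = grp.sort_values("temperature")
        ref = grp["rel_abundance"].iloc[0]
        if not np.isfinite(ref) or ref <= 0:
            dropped += 1
            continue
        grp = grp.assign(rel_abundance=grp["rel_abundance"] / ref)
        pieces.append(grp)
    if not pieces:
        raise ConfigError("no usable curves after reference-temperature scaling")
    df = pd.concat(pieces, ignore_index=True)

    fits = fit_all_curves(df)
    ok = fits[(fits["r_squared"] > r2_min) & (fits["plateau"] < plateau_max) & fits["converged"]]
    norm_proteins = set(ok["protein"])
    sub = df[df["protein"].isin(norm_proteins)]
    if sub.empty:
        raise ConfigError("normalization set is empty (no well-behaved curves)")

    med = (
        sub.groupby(["condition", "replicate", "temperature"])["rel_abundance"]
        .median()
        .rename("median")
        .reset_index()
    )
    if reference_condition is None:
        reference_condition = sorted(df["condition"].unique())[0]
    ref_med = (
        sub[sub["condition"] == reference_condition]
        .groupby("temperature")["rel_abundance"]
        .median()
    )
    # the per-trace scaling to 1 at the reference temperature takes curves a
    # hair outside the pure sigmoid family, so the target fit carries a free
    # overall scale (absorbed into the correction factors)
    def scaled_model(T, s, a, b, p):
        return s * melt_model(T, a, b, p)

    ref_fit = fit_melting_curve(ref_med.index.values, ref_med.values)
    if not ref_fit.converged:
        raise FitError("could not fit the reference-condition median melt curve")
    try:
        popt, _ = curve_fit(
            scaled_model, ref_med.index.values, ref_med.values,
            p0=[1.0, ref_fit.a, ref_fit.b, ref_fit.plateau],
            bounds=([0.5, 1e-6, 1e-6, 0.0], [2.0, np.inf, 500.0, 0.499]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        popt = [1.0, ref_fit.a, ref_fit.b, ref_fit.plateau]
    med["target"] = scaled_model(med["temperature"].values, *popt)
    med["factor"] = med["target"] / med["median"]

    factors = med[["condition", "replicate", "temperature", "factor"]]
    out = df.merge(factors, on=["condition", "replicate", "temperature"], how="left")
    out["rel_abundance"] = out["rel_abundance"] * out["factor"].fillna(1.0)
    out = out.drop(columns="factor")
    factors.attrs["dropped_curves"] = dropped
    return out, factors


@dataclass
class TPPComparison:
    """Per-protein melting-temperature shift between two conditions."""

    protein: str
    delta_tms: tuple          # per-replicate tm(cond2) - tm(cond1)
    mean_delta_tm: float
    sd_delta_tm: float
    n_usable: int
    n_excluded: int
    sign_consistent: bool
    usable: bool


def delta_tm(fits1: dict, fits2: dict, protein: str = "") -> TPPComparison:
    """Pair replicate fits of two conditions and summarize the Tm shift.

    ``fits1``/``fits2`` map replicate index -> :class:`MeltFit`; replicates
    with either fit unconverged are excluded and counted.  A comparison with
    fewer than two usable pairs is flagged unusable.
    """
    reps = sorted(set(fits1) | set(fits2))
    deltas, excluded = [], 0
    for rep in reps:
        f1, f2 = fits1.get(rep), fits2.get(rep)
        if f1 is None or f2 is None or not (f1.converged and f2.converged):
            excluded += 1
            continue
        deltas.append(f2.tm - f1.tm)
    n = len(deltas)
    if n < 2:
        return TPPComparison(protein, tuple(deltas), np.nan, np.nan, n, excluded, False, False)
    arr = np.asarray(deltas)
    sign_ok = bool(np.all(arr > 0) or np.all(arr < 0))
    return TPPComparison(
        protein,
        tuple(deltas),
        float(arr.mean()),
        float(arr.std(ddof=1)),
        n,
        excluded,
        sign_ok,
        True,
    )


def compare_conditions(fits: pd.DataFrame, condition1: str, condition2: str) -> list[TPPComparison]:
    """Per-protein Tm shifts (condition2 - condition1) from a fits table."""
    out = []
    for prot, grp in fits.groupby("protein"):
        d = {}
        for cond in (condition1, condition2):
            sub = grp[grp["condition"] == cond]
            d[cond] = {
                int(r.replicate): MeltFit(r.a, r.b, r.plateau, r.tm, r.r_squared, bool(r.converged))
                for r in sub.itertuples()
            }
        out.append(delta_tm(d[condition1], d[condition2], protein=str(prot)))
    return out


def call_tpp_hits(
    comparisons,
    min_abs_delta: float = 2.0,
    max_sd: float = 2.0,
    require_all_replicates: int = 4,
) -> pd.DataFrame:
    """Apply the replicate-consistency hit rule and rank by |mean dTm|.

    A protein is a hit iff all ``require_all_replicates`` replicate pairs are
    usable, every per-replicate shift has the same sign, |mean dTm| >=
    ``min_abs_delta`` and SD(dTm) < ``max_sd`` (both degC).
    """
    rows = []
    for c in comparisons:
        hit = (
            c.usable
            and c.n_usable >= require_all_replicates
            and c.sign_consistent
            and abs(c.mean_delta_tm) >= min_abs_delta
            and c.sd_delta_tm < max_sd
        )
        rows.append(
            {
                "protein": c.protein,
                "mean_delta_tm": c.mean_delta_tm,
                "sd_delta_tm": c.sd_delta_tm,
                "n_usable": c.n_usable,
                "sign_consistent": c.sign_consistent,
                "hit": bool(hit),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            "mean_delta_tm", key=lambda s: s.abs(), ascending=False
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# isothermal dose-response
# ---------------------------------------------------------------------------


def itdr_model(c, b0, bmax, ec50, hill=1.0):
    """Rising stabilization logistic; c -> 0 gives b0, c -> inf gives bmax."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (ec50 / np.where(c > 0, c, 1.0)) ** hill, np.inf)
    return b0 + (bmax - b0) / (1.0 + ratio)


@dataclass
class ITDRFit:
    """Fitted isothermal dose-response parameters."""

    b0: float
    bmax: float
    ec50: float
    hill: float
    r_squared: float
    se: dict
    hill_fixed: bool


def fit_itdr(concentrations, soluble_fractions, fix_hill: float | None = None) -> ITDRFit:
    """Fit the rising logistic to a soluble-fraction concentration series.

    Requires >= 5 points including a zero/near-zero concentration anchor.
    Weighted least squares with relative (constant-CV) weights, multi-start
    on an EC50 grid spanning the observed concentrations, soluble-fraction
    bounds [0, 1.2] on the plateaus.  With five or fewer distinct
    concentrations the Hill slope is fixed at 1 (four free parameters would
    be unidentifiable); pass ``fix_hill`` to override.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(soluble_fractions, dtype=float)
    if len(c) != len(y):
        raise ConfigError("concentration and fraction lengths differ")
    if len(c) < 5:
        raise ConfigError("need >= 5 concentration points")
    pos = c[c > 0]
    if len(pos) == 0 or np.ptp(y) == 0:
        raise FitError("degenerate series: no positive concentrations or flat response")
    uniq = np.unique(c)
    if fix_hill is None and len(uniq) <= 5:
        fix_hill = 1.0

    sigma = np.clip(np.abs(y), np.max(np.abs(y)) * 0.05, None)  # relative weights
    ec_grid = np.geomspace(pos.min(), pos.max(), 5)
    lo_y, hi_y = float(min(y.min(), 0.0)), float(y.max())
    best = None
    for ec0 in ec_grid:
        if fix_hill is not None:
            h = float(fix_hill)
            model = lambda cc, b0, bmax, ec: itdr_model(cc, b0, bmax, ec, h)  # noqa: E731
            p0 = [max(lo_y, 0.01), hi_y, ec0]
            bounds = ([0.0, 0.0, pos.min() / 100], [1.2, 1.2, pos.max() * 100])
        else:
            model = itdr_model
            p0 = [max(lo_y, 0.01), hi_y, ec0, 1.0]
            bounds = ([0.0, 0.0, pos.min() / 100, 0.2], [1.2, 1.2, pos.max() * 100, 5.0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, c, y, p0=p0, sigma=sigma, absolute_sigma=False,
                    bounds=bounds, maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(c, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitError(
            f"ITDR fit failed to converge from {len(ec_grid)} starts "
            f"(n={len(c)}, response span {np.ptp(y):.3g})"
        )
    ssr, popt, pcov = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    if fix_hill is not None:
        b0, bmax, ec50 = popt
        se = dict(zip(("b0", "bmax", "ec50"), ses))
        return ITDRFit(float(b0), float(bmax), float(ec50), float(fix_hill), r2, se, True)
    b0, bmax, ec50, hill = popt
    se = dict(zip(("b0", "bmax", "ec50", "hill"), ses))
    return ITDRFit(float(b0), float(bmax), float(ec50), float(hill), r2, se, False)
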