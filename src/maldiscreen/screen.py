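"""Screen QC (Z', replicate R^2), hit calling, and 4PL dose-response fitting.

The screening-window coefficient Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos -
mean_neg| is computed per compound set from that set's own control wells
(one full-inhibitor positive and one stimulated negative control per set,
one value per biological replicate after technical averaging) and summarized
as the across-set mean.  Hits are compounds whose mean percent effect over
the biological replicates reaches the cutoff (default 40%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .errors import FitError, ParameterError
from .phenotype import (
    add_percent_effect,
    aggregate_technical,
    normalize_ratio,
    quantify_spectra,
)
from .preprocess import ProcessingParams

__all__ = [
    "zprime",
    "call_hits",
    "replicate_r2",
    "ScreenResult",
    "analyze_screen",
    "screen_from_spectra",
    "DoseResponseFit",
    "fit_dose_response",
]


def zprime(positive, negative) -> float:
    """Screening-window coefficient from control distributions (sample SDs).

    Returns ``-inf`` with a warning when the group means coincide (the
    window is undefined).
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 3 or len(neg) < 3:
        raise ParameterError("each control group needs n >= 3")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        warnings.warn("equal control means: Z' undefined", stacklevel=2)
        return -np.inf
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def call_hits(effects, cutoff: float = 40.0) -> list[str]:
    """Compounds whose mean percent effect reaches the cutoff (ties included).

    ``effects`` maps compound -> mean percent effect (dict or Series).
    Returns compounds ordered by effect descending (deterministic: ties by
    compound id).
    """
    if isinstance(effects, pd.Series):
        effects = effects.to_dict()
    chosen = [(cid, e) for cid, e in effects.items() if e >= cutoff]
    chosen.sort(key=lambda t: (-t[1], t[0]))
    return [cid for cid, _ in chosen]


def replicate_r2(effects1, effects2) -> float:
    """Squared Pearson correlation of paired per-compound effects."""
    x = np.asarray(effects1, dtype=float)
    y = np.asarray(effects2, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero variance in a replicate vector; R^2 undefined")
    r, _ = pearsonr(x, y)
    return float(r * r)


@dataclass
class ScreenResult:
    """Everything the screen analysis produces."""

    effects: pd.Series                 # compound -> mean percent effect
    effects_by_replicate: pd.DataFrame  # compounds x biological replicates
    per_set_zprime: dict               # (plate, set) -> Z'
    zprime: float                      # across-set mean
    r2_pairs: dict                     # (rep_i, rep_j) -> R^2
    replicate_r2: float                # mean over replicate pairs
    hits: list = field(default_factory=list)
    cutoff: float = 40.0
    well_table: pd.DataFrame | None = None


def analyze_screen(quants: pd.DataFrame, cutoff: float = 40.0) -> ScreenResult:
    """Full screen analysis from a per-spectrum quantification table.

    Steps: technical averaging -> plate normalization to stimulated controls
    -> per-set percent effect -> per-set Z' (one control value per biological
    replicate) -> pairwise replicate R^2 on per-compound effects -> hit
    calling on the across-replicate mean effect.
    """
    wells = aggregate_technical(quants)
    wells = normalize_ratio(wells)
    wells = add_percent_effect(wells)

    zp = {}
    for (plate, set_id), grp in wells.groupby(["plate", "set"], dropna=False):
        pos = grp[grp["role"] == "positive_control"]["normalized_ratio"].values
        neg = grp[grp["role"] == "negative_control"]["normalized_ratio"].values
        key = (plate, set_id)
        zp[key] = (pos, neg)
    # controls per set pooled across plates: one value per biological replicate
    per_set = {}
    sets = sorted({s for (_, s) in zp})
    for set_id in sets:
        pos = np.concatenate([v[0] for (p, s), v in zp.items() if s == set_id])
        neg = np.concatenate([v[1] for (p, s), v in zp.items() if s == set_id])
        per_set[set_id] = zprime(pos, neg)
    z_mean = float(np.mean(list(per_set.values()))) if per_set else np.nan

    tests = wells[wells["role"] == "test"]
    eff = tests.pivot_table(
        index="compound", columns="biological_replicate", values="percent_effect"
    )
    r2_pairs = {}
    reps = list(eff.columns)
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            r2_pairs[(reps[i], reps[j])] = replicate_r2(
                eff[reps[i]].values, eff[reps[j]].values
            )
    r2_mean = float(np.mean(list(r2_pairs.values()))) if r2_pairs else np.nan

    mean_eff = eff.mean(axis=1)
    hits = call_hits(mean_eff, cutoff)
    return ScreenResult(
        effects=mean_eff,
        effects_by_replicate=eff,
        per_set_zprime=per_set,
        zprime=z_mean,
        r2_pairs=r2_pairs,
        replicate_r2=r2_mean,
        hits=hits,
        cutoff=cutoff,
        well_table=wells,
    )


def screen_from_spectra(
    spectra,
    params: ProcessingParams | None = None,
    cutoff: float = 40.0,
) -> ScreenResult:
    """Convenience: quantify annotated spectra and analyze the screen."""
    return analyze_screen(quantify_spectra(spectra, params), cutoff)


def analyze_dose_series(quants: pd.DataFrame):
    """Concentration-response from a quantified inhibitor titration.

    Averages percent effect per concentration across biological replicates
    and fits the rising (stimulation-orientation) 4PL; returns
    ``(concentrations, mean_effects, DoseResponseFit)``.
    """
    wells = aggregate_technical(quants)
    wells = normalize_ratio(wells)
    wells = add_percent_effect(wells)
    tests = wells[(wells["role"] == "test") & wells["concentration"].notna()]
    eff = tests.groupby("concentration")["percent_effect"].mean().sort_index()
    fit = fit_dose_response(eff.index.values, eff.values, orientation="stimulation")
    return eff.index.values, eff.values, fit


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit of a concentration-response series."""

    top: float
    bottom: float
    ic50: float
    hill: float
    r_squared: float
    se: dict
    orientation: str


def _4pl(logc, top, bottom, log_ic50, hill):
    # inhibition orientation: response falls from `top` to `bottom` with c
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - log_ic50) * np.log(10)))


def fit_dose_response(concentrations, responses, orientation: str = "stimulation") -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration with multi-start IC50.

    ``orientation='stimulation'`` models a response rising with concentration
    (e.g. percent effect of an inhibitor); ``'inhibition'`` a falling one.
    Needs >= 5 positive concentrations spanning the transition; constant
    responses raise :class:`FitError`.  IC50 is reported in the input
    concentration unit; parameter SEs come from the fit covariance.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if orientation not in ("stimulation", "inhibition"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    if len(c) != len(y):
        raise ParameterError("concentration and response lengths differ")
    ok = c > 0
    if ok.sum() < 5:
        raise ParameterError("need >= 5 positive concentration points")
    c, y = c[ok], y[ok]
    if np.ptp(y) == 0:
        raise FitError("constant responses: no transition to fit")
    logc = np.log10(c)
    ysign = -y if orientation == "stimulation" else y  # fit falling curve
    span = np.ptp(ysign)

    best = None
    for lic in np.linspace(logc.min(), logc.max(), 7):
        p0 = [ysign.max(), ysign.min(), lic, 1.0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _4pl, logc, ysign, p0=p0,
                    bounds=(
                        [ysign.min() - span, ysign.min() - span, logc.min() - 3, 0.1],
                        [ysign.max() + span, ysign.max() + span, logc.max() + 3, 10.0],
                    ),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((_4pl(logc, *popt) - ysign) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitError(
            f"dose-response fit failed from 7 starts (n={len(c)}, "
            f"range {c.min():.3g}-{c.max():.3g})"
        )
    ssr, (top_s, bottom_s, log_ic50, hill), pcov = best
    sst = float(np.sum((ysign - ysign.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    ic50 = 10.0**log_ic50
    ic50_se = float(ses[2] * ic50 * np.log(10))  # delta method
    if orientation == "stimulation":
        top, bottom = -bottom_s, -top_s
    else:
        top, bottom = top_s, bottom_s
    se = {"top": float(ses[0]), "bottom": float(ses[1]), "ic50": ic50_se, "hill": float(ses[3])}
    return DoseResponseFit(
        float(top), float(bottom), float(ic50), float(hill), r2, se, orientation
    )
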