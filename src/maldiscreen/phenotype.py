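"""Biomarker ratio statistic, percent effect, group tests and PCA fingerprints.

The assay's decision statistic is intraspectral: the area of the
TLR-stimulation marker at m/z 4964 divided by the area of the resting marker
at m/z 4632.  Because both areas come from the same spectrum, any overall
intensity normalization cancels in the quotient, which is what makes the
statistic robust to shot-to-shot MALDI intensity variation.  The third
feature at m/z 6891 is quantified and reported but excluded from the
decision statistic (it is the more variable marker between replicates).

Ratios are normalized per plate to the mean of the stimulated
negative-control wells (so the full inflammatory phenotype sits at 1), and a
test well's percent effect rescales its normalized ratio between its own
compound set's negative-control mean (0% = no effect) and positive-control
mean (100% = full inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import MissingControlError, ParameterError
from .io import Spectrum
from .preprocess import ProcessingParams, bin_spectrum, default_halfwidth, integrate_feature, preprocess

RESTING_MARKER = 4632.0
STIMULATED_MARKER = 4964.0
VARIABLE_MARKER = 6891.0
FEATURE_MZ = (RESTING_MARKER, STIMULATED_MARKER, VARIABLE_MARKER)

__all__ = [
    "FEATURE_MZ",
    "FeatureQuant",
    "compute_ratio",
    "quantify_spectra",
    "aggregate_technical",
    "normalize_ratio",
    "percent_effect",
    "add_percent_effect",
    "PCAResult",
    "pca_fingerprint",
    "top_loadings",
    "separating_component",
    "mann_whitney",
    "significance_tier",
]


@dataclass
class FeatureQuant:
    """Per-well integrated biomarker areas and derived statistics."""

    plate: str
    well: str
    role: str
    compound: str | None
    set: str | None
    technical_replicate: int
    biological_replicate: int
    area_4632: float
    area_4964: float
    area_6891: float
    raw_ratio: float = np.nan
    normalized_ratio: float = np.nan
    percent_effect: float = np.nan
    flags: str = ""


def compute_ratio(area_4964: float, area_4632: float) -> float:
    """Raw stimulation ratio A(4964) / A(4632); NaN when the denominator is 0.

    Relative-peak-area normalization (each area over the spectrum total)
    cancels in the quotient, so the direct area ratio is the implemented
    statistic.
    """
    if area_4632 <= 0:
        return np.nan
    return area_4964 / area_4632


def quantify_spectra(
    spectra,
    params: ProcessingParams | None = None,
    features=FEATURE_MZ,
) -> pd.DataFrame:
    """Preprocess each spectrum and integrate the biomarker windows.

    Returns one row per spectrum with its plate-map metadata, the three
    feature areas, the raw ratio, and a ``zero_denominator`` flag where the
    resting-marker area vanished (such rows are excluded from statistics
    downstream).
    """
    params = params or ProcessingParams()
    rows = []
    for spec in spectra:
        proc = preprocess(spec, params)
        areas = {}
        for mz in features:
            hw = params.integration_halfwidth or default_halfwidth(mz)
            areas[f"area_{int(mz)}"] = integrate_feature(proc, mz, hw)
        ratio = compute_ratio(areas["area_4964"], areas["area_4632"])
        row = {
            "plate": spec.metadata.get("plate", "P1"),
            "well": spec.metadata.get("well", ""),
            "role": spec.metadata.get("role", "test"),
            "compound": spec.metadata.get("compound"),
            "set": spec.metadata.get("set"),
            "concentration": spec.metadata.get("concentration"),
            "technical_replicate": spec.metadata.get("technical_replicate", 1),
            "biological_replicate": spec.metadata.get("biological_replicate", 1),
            **areas,
            "raw_ratio": ratio,
            "flags": "" if np.isfinite(ratio) else "zero_denominator",
        }
        rows.append(row)
    return pd.DataFrame(rows)


_WELL_KEY = [
    "plate", "well", "role", "compound", "set", "concentration", "biological_replicate",
]


def aggregate_technical(quants: pd.DataFrame) -> pd.DataFrame:
    """Average technical-replicate spectra to one row per well.

    Areas and the per-spectrum ratios are averaged (the ratio is intraspectral,
    so the mean of ratios is the natural technical summary); flagged spectra
    are dropped first.
    """
    ok = quants[quants["flags"].fillna("") == ""].copy()
    if ok.empty:
        raise ParameterError("no unflagged quantifications to aggregate")
    grouped = ok.groupby(_WELL_KEY, dropna=False, as_index=False).agg(
        area_4632=("area_4632", "mean"),
        area_4964=("area_4964", "mean"),
        area_6891=("area_6891", "mean"),
        raw_ratio=("raw_ratio", "mean"),
        n_technical=("raw_ratio", "size"),
    )
    return grouped


def normalize_ratio(quants: pd.DataFrame) -> pd.DataFrame:
    """Divide each raw ratio by the plate's stimulated negative-control mean.

    After normalization the stimulated phenotype centers at 1 on every plate.
    Raises :class:`MissingControlError` when a plate has fewer than two
    negative-control wells.
    """
    out = quants.copy()
    out["normalized_ratio"] = np.nan
    for plate, grp in out.groupby("plate"):
        negs = grp[grp["role"] == "negative_control"]["raw_ratio"].dropna()
        if len(negs) < 2:
            raise MissingControlError(
                f"plate {plate!r} has {len(negs)} negative-control wells; need >= 2"
            )
        out.loc[grp.index, "normalized_ratio"] = grp["raw_ratio"] / negs.mean()
    return out


def percent_effect(normalized_ratio, pos_mean: float, neg_mean: float):
    """Rescale a normalized ratio between set controls: 0% = stimulated, 100% = inhibited."""
    if pos_mean == neg_mean:
        raise ParameterError("degenerate controls: positive and negative means equal")
    return 100.0 * (neg_mean - np.asarray(normalized_ratio)) / (neg_mean - pos_mean)


def add_percent_effect(quants: pd.DataFrame) -> pd.DataFrame:
    """Percent effect for test wells, anchored to their own set's controls.

    Controls are taken per (plate, set) -- the staggered-set design -- from
    the same normalized-ratio table; control and vehicle wells keep NaN.
    """
    out = quants.copy()
    out["percent_effect"] = np.nan
    for (plate, set_id), grp in out.groupby(["plate", "set"], dropna=False):
        pos = grp[grp["role"] == "positive_control"]["normalized_ratio"].dropna()
        neg = grp[grp["role"] == "negative_control"]["normalized_ratio"].dropna()
        if pos.empty or neg.empty:
            raise MissingControlError(
                f"set {set_id!r} on plate {plate!r} lacks positive/negative controls"
            )
        mask = grp["role"] == "test"
        out.loc[grp.index[mask], "percent_effect"] = percent_effect(
            grp.loc[mask, "normalized_ratio"].values, pos.mean(), neg.mean()
        )
    return out


# ---------------------------------------------------------------------------
# PCA fingerprinting
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Principal components of binned spectra (wells x bins)."""

    scores: np.ndarray            # wells x components
    loadings: np.ndarray          # bins x components, orthonormal columns
    explained_variance: np.ndarray  # fractions, non-increasing
    bin_centers: np.ndarray = field(default=None)


def pca_fingerprint(vectors, n_components: int = 2, bin_centers=None) -> PCAResult:
    """Standard PCA of mean-centered binned spectra (no variance scaling).

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are reproducible across library versions.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with >= 2 wells")
    if n_components > min(X.shape):
        raise ParameterError(
            f"cannot extract {n_components} components from {X.shape[0]} wells"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero total variance -> 0/0
        scores = pca.fit_transform(X)
    explained = np.nan_to_num(pca.explained_variance_ratio_)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        bin_centers=None if bin_centers is None else np.asarray(bin_centers, dtype=float),
    )


def top_loadings(result: PCAResult, component: int = 0, k: int = 10):
    """k (bin center, loading) pairs sorted by |loading| desc, ties to lower m/z."""
    load = result.loadings[:, component]
    centers = (
        result.bin_centers
        if result.bin_centers is not None
        else np.arange(len(load), dtype=float)
    )
    if k > len(load):
        import warnings

        warnings.warn(f"k={k} exceeds {len(load)} bins; truncating", stacklevel=2)
        k = len(load)
    order = np.lexsort((centers, -np.abs(load)))[:k]
    return [(float(centers[i]), float(load[i])) for i in order]


def separating_component(result: PCAResult, labels) -> int:
    """Index of the component whose scores best separate two label groups.

    Criterion: largest absolute standardized mean difference between groups.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ParameterError("separating_component needs exactly two label groups")
    best, best_stat = 0, -np.inf
    for j in range(result.scores.shape[1]):
        a = result.scores[labels == groups[0], j]
        b = result.scores[labels == groups[1], j]
        pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
        stat = np.inf if pooled == 0 else abs(a.mean() - b.mean()) / pooled
        if stat > best_stat:
            best, best_stat = j, stat
    return best


def bin_spectra_matrix(spectra, bin_width: float = 5.0, mass_range=(2000.0, 20000.0)):
    """Stack TIC-normalized binned vectors for a set of spectra."""
    centers = None
    vecs = []
    for spec in spectra:
        c, v = bin_spectrum(spec, bin_width, mass_range)
        centers = c
        vecs.append(v)
    return centers, np.vstack(vecs)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def significance_tier(p: float) -> str:
    """Figure-legend style tiers: *** <=0.001, ** <=0.01, * <=0.05, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class MannWhitneyResult:
    u: float
    pvalue: float
    tier: str
    method: str


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the U null distribution when both groups are
    small (min n <= 8) and tie-free; normal approximation with tie correction
    (and continuity correction) otherwise.  Groups of fewer than 3 values are
    refused.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        return MannWhitneyResult(len(a) * len(b) / 2.0, 1.0, "ns", "degenerate")
    method = "exact" if (not has_ties and min(len(a), len(b)) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return MannWhitneyResult(float(res.statistic), p, significance_tier(p), method)
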