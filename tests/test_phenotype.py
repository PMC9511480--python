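"""Ratio statistic, normalization, percent effect, PCA, Mann-Whitney."""

import itertools

import numpy as np
import pandas as pd
import pytest

from maldiscreen import phenotype as ph
from maldiscreen import simulate
from maldiscreen.errors import MissingControlError, ParameterError
from maldiscreen.phenotype import (
    bin_spectra_matrix,
    compute_ratio,
    mann_whitney,
    pca_fingerprint,
    percent_effect,
    quantify_spectra,
    separating_component,
    top_loadings,
)


class TestRatio:
    def test_basic_quotient(self):
        assert compute_ratio(2.0, 1.0) == 2.0
        assert compute_ratio(3.0, 3.0) == 1.0

    def test_zero_denominator_flagged_as_nan(self):
        assert np.isnan(compute_ratio(2.0, 0.0))

    def test_noiseless_lps_vs_resting_is_threefold(self, noiseless_config):
        spectra = [
            simulate.generate_spectrum(
                noiseless_config, cond, seed=0,
                metadata={"well": cond, "role": "test", "plate": "P1", "set": "S1"},
            )
            for cond in ("LPS", "resting")
        ]
        q = quantify_spectra(spectra)
        lps, rest = q["raw_ratio"].values
        assert lps / rest == pytest.approx(3.0, rel=0.01)

    def test_ratio_invariant_to_intensity_scale(self, small_config):
        spec = simulate.generate_spectrum(small_config, "LPS", seed=4)
        scaled = spec.copy_with(spec.intensity * 17.0)
        r1 = quantify_spectra([spec])["raw_ratio"].iloc[0]
        r2 = quantify_spectra([scaled])["raw_ratio"].iloc[0]
        assert r1 == pytest.approx(r2, rel=1e-9)


def _well_frame(ratios_by_role):
    rows = []
    for (role, plate, set_id), ratios in ratios_by_role.items():
        for i, r in enumerate(ratios):
            rows.append(
                {
                    "plate": plate, "well": f"{set_id}-{role[:3]}{i}", "role": role,
                    "compound": f"C{i:03d}" if role == "test" else None,
                    "set": set_id, "concentration": None,
                    "biological_replicate": 1, "raw_ratio": r,
                }
            )
    return pd.DataFrame(rows)


class TestNormalization:
    def test_negative_controls_center_at_one(self):
        df = _well_frame({("negative_control", "P1", "S1"): [2.0, 2.2, 1.8]})
        out = ph.normalize_ratio(df)
        negs = out[out["role"] == "negative_control"]["normalized_ratio"]
        assert negs.mean() == pytest.approx(1.0)

    def test_identical_wells_all_one(self):
        df = _well_frame(
            {
                ("negative_control", "P1", "S1"): [1.5, 1.5],
                ("test", "P1", "S1"): [1.5, 1.5, 1.5],
            }
        )
        out = ph.normalize_ratio(df)
        assert np.allclose(out["normalized_ratio"], 1.0)

    def test_missing_controls_refused(self):
        df = _well_frame({("test", "P1", "S1"): [1.0, 1.1]})
        with pytest.raises(MissingControlError):
            ph.normalize_ratio(df)

    def test_unstimulated_wells_fall_below_one(self, small_config):
        # vehicle (resting) wells must sit below the stimulated center
        spectra = []
        for i in range(3):
            for cond, role in (("LPS", "negative_control"), ("resting", "vehicle")):
                spectra.append(
                    simulate.generate_spectrum(
                        small_config, cond, seed=100 + 7 * i + (role == "vehicle"),
                        metadata={
                            "well": f"{role}{i}", "role": role, "plate": "P1", "set": "S1",
                        },
                    )
                )
        q = ph.normalize_ratio(quantify_spectra(spectra))
        veh = q[q["role"] == "vehicle"]["normalized_ratio"]
        assert (veh < 1.0).all()


class TestPercentEffect:
    def test_anchors(self):
        assert percent_effect(1.0, pos_mean=0.4, neg_mean=1.0) == 0.0
        assert percent_effect(0.4, pos_mean=0.4, neg_mean=1.0) == 100.0
        assert percent_effect(0.7, pos_mean=0.4, neg_mean=1.0) == pytest.approx(50.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, pos, neg = rng.normal(1.0, 0.2, 5), 0.4, 1.1
        base = percent_effect(x, pos, neg)
        a, b = 3.7, -2.0
        shifted = percent_effect(a * x + b, a * pos + b, a * neg + b)
        assert np.allclose(base, shifted)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ParameterError):
            percent_effect(0.5, pos_mean=1.0, neg_mean=1.0)


class TestPCA:
    def test_identical_spectra_have_zero_scores(self):
        X = np.tile(np.array([0.2, 0.3, 0.5]), (4, 1))
        res = pca_fingerprint(X, n_components=2)
        assert np.allclose(res.scores, 0.0)

    def test_noiseless_two_condition_data_has_one_component(self, noiseless_config):
        spectra = [
            simulate.generate_spectrum(noiseless_config, cond, seed=i)
            for i, cond in enumerate(["resting"] * 3 + ["LPS"] * 3)
        ]
        _, X = bin_spectra_matrix(spectra, 5.0, noiseless_config.mass_range)
        res = pca_fingerprint(X, n_components=3)
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.explained_variance[1:] < 1e-9)

    def test_loadings_are_orthonormal_and_variance_sorted(self, small_config):
        spectra = [
            simulate.generate_spectrum(small_config, cond, seed=200 + i)
            for i, cond in enumerate(["resting"] * 4 + ["LPS"] * 4)
        ]
        _, X = bin_spectra_matrix(spectra, 5.0, small_config.mass_range)
        res = pca_fingerprint(X, n_components=3)
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(3), atol=1e-9)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)
        assert res.explained_variance.sum() <= 1.0 + 1e-9

    def test_condition_clusters_separate_on_leading_component(self, small_config):
        from sklearn.metrics import silhouette_score

        labels = ["resting"] * 8 + ["LPS"] * 8
        spectra = [
            simulate.generate_spectrum(small_config, cond, seed=300 + i)
            for i, cond in enumerate(labels)
        ]
        centers, X = bin_spectra_matrix(spectra, 5.0, small_config.mass_range)
        res = pca_fingerprint(X, n_components=2, bin_centers=centers)
        comp = separating_component(res, labels)
        score = silhouette_score(
            res.scores[:, [comp]], np.asarray(labels) == "LPS"
        )
        assert score > 0.5

    def test_biomarker_bins_dominate_the_separating_loadings(self, small_config):
        labels = ["resting"] * 8 + ["LPS"] * 8
        spectra = [
            simulate.generate_spectrum(small_config, cond, seed=400 + i)
            for i, cond in enumerate(labels)
        ]
        centers, X = bin_spectra_matrix(spectra, 5.0, small_config.mass_range)
        res = pca_fingerprint(X, n_components=2, bin_centers=centers)
        comp = separating_component(res, labels)
        top = [mz for mz, _ in top_loadings(res, comp, 5)]
        # bins are 5 Da wide and centers are reported; both biomarkers present
        assert any(abs(mz - 4632.0) <= 5.0 for mz in top)
        assert any(abs(mz - 4964.0) <= 5.0 for mz in top)

    def test_top_loadings_edge_cases(self):
        res = pca_fingerprint(np.array([[1.0], [2.0], [3.0]]), n_components=1)
        assert top_loadings(res, 0, 0) == []
        single = top_loadings(res, 0, 1)
        assert len(single) == 1
        with pytest.warns(UserWarning):
            assert len(top_loadings(res, 0, 5)) == 1

    def test_too_few_wells_rejected(self):
        with pytest.raises(ParameterError):
            pca_fingerprint(np.ones((2, 10)), n_components=3)


def brute_force_mannwhitney_p(a, b):
    """Exact two-sided p by enumerating group assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(idx):
        ra = sum(ranks[pooled[i]] for i in idx)
        return ra - n * (n + 1) / 2

    u_obs = u_of(range(n))
    nab = len(a) * len(b)
    dist = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n)]
    extreme = sum(
        1 for u in dist if min(u, nab - u) <= min(u_obs, nab - u_obs)
    )
    return extreme / len(dist)


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        res = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.pvalue == 1.0
        assert res.tier == "ns"

    def test_fully_separated_triplets(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.pvalue == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, rng.integers(3, 7))
        b = rng.normal(0.8, 1.0, rng.integers(3, 7))
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(brute_force_mannwhitney_p(a, b), abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_tier_thresholds(self):
        assert ph.significance_tier(0.2) == "ns"
        assert ph.significance_tier(0.04) == "*"
        assert ph.significance_tier(0.009) == "**"
        assert ph.significance_tier(0.0005) == "***"
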