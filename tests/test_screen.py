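"""Normalization cascade and hit selection against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA as SKPCA

from neuromat import (LibrarySpec, ScreenConfig, bscore, dose_response,
                      median_polish, pair_plates, pca_hits, robust_z,
                      score_screen, simulate_screen_features,
                      single_param_hits, validation_score, viability_filter,
                      zscore)
from neuromat.screen import PARAMS, orient_components


# --------------------------------------------------------------------------
# independent median-polish oracle: plain nested loops, no shared code
# --------------------------------------------------------------------------

def polish_oracle(mat, n_sweeps=400):
    r = [row[:] for row in mat]
    nr, nc = len(r), len(r[0])

    def med(vals):
        vals = sorted(v for v in vals if v == v)  # drop NaN
        if not vals:
            return 0.0
        k = len(vals)
        return (vals[k // 2] if k % 2 else
                0.5 * (vals[k // 2 - 1] + vals[k // 2]))

    for _ in range(n_sweeps):
        for i in range(nr):
            m = med(r[i])
            for j in range(nc):
                r[i][j] -= m
        for j in range(nc):
            m = med([r[i][j] for i in range(nr)])
            for i in range(nr):
                r[i][j] -= m
    return np.array(r)


class TestPairPlates:
    def _features(self, stim_frac, unstim_frac):
        rows = []
        for cond, frac in (("stim", stim_frac), ("unstim", unstim_frac)):
            rows.append({"plate": "P01", "well": "B02", "row": 1, "col": 1,
                         "condition": cond, "compound_id": "C0001",
                         "replicate": 1, "nucleus_area": 100.0,
                         "nucleus_roundness": 0.9, "neurite_length": 500.0,
                         "n_segments": 10.0, "frac_fos": frac,
                         "frac_egr1": frac, "frac_double": frac,
                         "nuclei_count": 1000.0})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("stim,unstim,expected", [
        (0.8, 0.2, 0.6), (0.5, 0.5, 0.0), (0.1, 0.4, -0.3)])
    def test_baseline_subtraction(self, stim, unstim, expected):
        paired = pair_plates(self._features(stim, unstim))
        assert paired["induced_frac_fos"].iloc[0] == pytest.approx(expected)

    def test_morphology_averaged(self):
        df = self._features(0.5, 0.1)
        df.loc[df.condition == "stim", "neurite_length"] = 600.0
        df.loc[df.condition == "unstim", "neurite_length"] = 400.0
        paired = pair_plates(df)
        assert paired["neurite_length"].iloc[0] == pytest.approx(500.0)

    def test_orphan_well_raises_with_address(self):
        df = self._features(0.5, 0.1)
        df = pd.concat([df, pd.DataFrame([{**df.iloc[0].to_dict(),
                                           "well": "C03"}])])
        with pytest.raises(ValueError, match="C03"):
            pair_plates(df)


class TestBScore:
    def test_constant_matrix_all_zero(self):
        b = bscore(np.full((4, 6), 7.0))
        assert np.allclose(b, 0.0)

    def test_2x2_hand_polish(self):
        # [[1,2],[3,4]]: row medians (1.5, 3.5), then column medians
        # (-0.5, 0.5) leave residuals exactly zero
        resid = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(resid, 0.0)

    def test_additive_artifacts_removed_spike_survives(self):
        rng = np.random.default_rng(1)
        row = rng.normal(0, 2, 16)
        col = rng.normal(0, 2, 24)
        m = row[:, None] + col[None, :] + rng.uniform(-0.3, 0.3, (16, 24))
        m[7, 11] += 10.0
        b = bscore(m)
        spiked = np.zeros_like(b, dtype=bool)
        spiked[7, 11] = True
        assert np.abs(b[spiked]) > 3
        assert np.abs(b[~spiked]).max() < 3

    def test_row_column_effects_visible_raw_gone_after_bscore(self):
        lib = LibrarySpec(n_compounds=330, n_toxic=0, n_hits=0,
                          row_effect_sd=3.0, col_effect_sd=0.0, seed=5)
        df = simulate_screen_features(lib).features
        one = df[(df.plate == "P01") & (df.condition == "stim")
                 & (df.replicate == 1)]
        m = np.full((16, 24), np.nan)
        m[one.row, one.col] = one.nucleus_area
        raw_row_spread = np.nanstd(np.nanmean(m, axis=1))
        b = bscore(m)
        b_row_spread = np.nanstd(np.nanmean(b, axis=1))
        assert raw_row_spread > 5 * b_row_spread

    def test_matches_brute_force_oracle_100_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = rng.normal(0, 1, (16, 24))
            resid = median_polish(m, max_iter=500, tol=1e-12)
            oracle = polish_oracle(m.tolist(), n_sweeps=500)
            assert np.max(np.abs(resid - oracle)) < 1e-6

    def test_residual_row_col_medians_vanish(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            resid = median_polish(rng.normal(0, 1, (8, 12)), max_iter=500,
                                  tol=1e-10)
            assert np.max(np.abs(np.median(resid, axis=0))) < 1e-6
            assert np.max(np.abs(np.median(resid, axis=1))) < 1e-6

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.array([[1.0, 2.0]]))


class TestZScore:
    def test_at_median_is_zero(self):
        assert robust_z([5.0], [4.0, 5.0, 6.0])[0] == 0.0

    def test_symmetric_reference_formula(self):
        z = robust_z([1.0], [-1.0, 0.0, 1.0])[0]
        assert z == pytest.approx(1 / 1.4826, abs=1e-4)

    def test_replicates_averaged(self):
        ref = np.arange(-10.0, 11.0)
        scale = 1.4826 * 5.0  # MAD of the integer ramp is 5
        z = zscore([np.array([2 * scale]), np.array([4 * scale])],
                   references=[ref, ref])
        assert z[0] == pytest.approx(3.0, rel=1e-6)

    def test_needs_three_reference_values(self):
        with pytest.raises(ValueError):
            robust_z([1.0], [1.0, 2.0])


class TestViabilityFilter:
    def test_strict_threshold(self):
        z = pd.Series({"a": -2.0, "b": -2.5, "c": 0.3})
        retained, excluded = viability_filter(z, threshold=-2.0)
        assert "a" in retained and "b" in excluded and "c" in retained

    def test_planted_toxic_excluded_exactly(self, screen_result,
                                            screen_truth):
        assert set(screen_result.excluded_toxic) == screen_truth["toxic"]
        assert len(screen_result.excluded_toxic) == 325


class TestPCA:
    def _zmatrix(self, seed=0, n=200, spike=10):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1, (n, 6))
        z[:spike] += 6.0  # all-six-elevated compounds
        ids = [f"C{i:04d}" for i in range(n)]
        return pd.DataFrame(z, index=ids, columns=list(PARAMS))

    def test_spiked_compounds_called_and_oracle_agreement(self):
        zm = self._zmatrix()
        res = pca_hits(zm, ScreenConfig())
        assert set(zm.index[:10]).issubset(set(res.hits_pca))
        # independent oracle: sklearn PCA on the same matrix
        sk = SKPCA(n_components=6).fit(zm.to_numpy())
        assert np.allclose(np.sort(res.explained_variance),
                           np.sort(sk.explained_variance_ratio_), atol=1e-8)
        for j in range(6):
            a = res.loadings.to_numpy()[:, j]
            b = sk.components_[j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_loadings_orthonormal_and_evr_sums_to_one(self, screen_result):
        L = screen_result.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-8)
        ev = screen_result.explained_variance
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_reconstruction_from_all_components(self):
        zm = self._zmatrix(seed=3)
        res = pca_hits(zm, ScreenConfig())
        X = zm.to_numpy()
        recon = (res.pc_scores.to_numpy() @ res.loadings.to_numpy().T
                 + X.mean(axis=0))
        assert np.max(np.abs(recon - X)) < 1e-6

    def test_scores_invariant_to_eigenvector_sign_flips(self):
        zm = self._zmatrix(seed=4)
        res = pca_hits(zm, ScreenConfig())
        L = res.loadings.to_numpy().copy()
        S = res.pc_scores.to_numpy().copy()
        flip = np.array([1, -1, 1, -1, -1, 1.0])
        L2, S2 = orient_components(L * flip, S * flip,
                                   list(PARAMS).index("induced_frac_fos"))
        assert np.allclose(L2, L) and np.allclose(S2, S)

    def test_pc1_fos_loading_positive(self, screen_result):
        assert screen_result.loadings.loc["induced_frac_fos", "PC1"] > 0

    def test_needs_seven_compounds(self):
        with pytest.raises(ValueError):
            pca_hits(self._zmatrix(n=6))

    def test_monotonicity_stronger_effect_higher_pc1(self):
        zm = self._zmatrix(seed=5)
        res = pca_hits(zm, ScreenConfig())
        zm2 = zm.copy()
        cid = zm.index[50]
        zm2.loc[cid] = zm2.loc[cid] + 2.0  # raise all six parameters
        res2 = pca_hits(zm2, ScreenConfig())
        assert res2.pc_scores.loc[cid, "PC1"] >= res.pc_scores.loc[cid, "PC1"]


class TestSingleParamHits:
    def _zm(self, neurite, double, ids=None):
        n = len(neurite)
        ids = ids or [f"C{i:02d}" for i in range(n)]
        z = pd.DataFrame(0.0, index=ids, columns=list(PARAMS)
                         + ["induced_frac_double", "viability"])
        z["neurite_length"] = neurite
        z["induced_frac_double"] = double
        return z

    def test_tie_break_by_compound_id(self):
        zm = self._zm([1.0] * 8, [0.0] * 8)
        hits = single_param_hits(zm, k=3)
        assert hits[:3] == sorted(zm.index)[:3]

    def test_disjoint_top5_yields_ten(self):
        neurite = [0.0] * 20
        double = [0.0] * 20
        for i in range(5):
            neurite[i] = 10 - i
            double[10 + i] = 10 - i
        zm = self._zm(neurite, double)
        hits = single_param_hits(zm, k=5)
        assert len(hits) == 10

    def test_overlap_yields_fewer_than_2k(self):
        neurite = [float(i) for i in range(20)]
        zm = self._zm(neurite, neurite)  # identical rankings
        hits = single_param_hits(zm, k=5)
        assert len(hits) == 5

    def test_excluded_ids_skipped(self):
        zm = self._zm([5.0, 4.0, 3.0, 0, 0, 0, 0, 0], [0.0] * 8)
        hits = single_param_hits(zm, k=2, exclude=[zm.index[0]])
        assert zm.index[0] not in hits
        assert zm.index[1] in hits


class TestEndToEndScreen:
    def test_hit_recall_and_toxic_exclusion(self, screen_result,
                                            screen_truth):
        called = set(screen_result.hits_pca)
        recall = len(called & screen_truth["hit"]) / len(screen_truth["hit"])
        assert recall >= 0.9
        assert not called & screen_truth["toxic"]

    def test_hits_disjoint_from_toxic_invariant(self, screen_result):
        assert not set(screen_result.hits_pca) & \
            set(screen_result.excluded_toxic)

    def test_single_param_hits_exclude_pca_hits(self, screen_result):
        assert not set(screen_result.hits_single_param) & \
            set(screen_result.hits_pca)

    def test_dmso_z_centered_with_unit_spread(self):
        """Control wells z-scored against the library: median 0, spread 1.

        Uses a toxic-free library so the reference distribution is not
        shifted by planted outliers.
        """
        plates = simulate_screen_features(
            LibrarySpec(n_toxic=0, n_hits=0, seed=17))
        paired = pair_plates(plates.features)
        rep = paired[paired.replicate == 1]
        dmso = rep[rep.compound_id == "DMSO"]["viability"].to_numpy()
        ref = rep[rep.compound_id != "DMSO"]["viability"].to_numpy()
        z = robust_z(dmso, ref)
        assert abs(np.median(z)) < 0.1
        spread = 1.4826 * np.median(np.abs(z - np.median(z)))
        assert 0.9 < spread < 1.1

    def test_cluster_labels_cover_result(self, screen_result):
        labels = set(screen_result.cluster_labels.unique())
        assert "maturation-enhancing" in labels
        assert labels <= {"maturation-enhancing", "maturation-inhibiting",
                          "non-neuronal-proliferation", "other"}


class TestValidation:
    def _paired(self, ratios):
        rows = []
        base = {"nucleus_area": 100.0, "nucleus_roundness": 0.8,
                "neurite_length": 500.0, "induced_frac_double": 0.2}
        for i in range(4):  # DMSO wells
            rows.append({"plate": "P01", "well": f"A{i+1:02d}",
                         "compound_id": "DMSO", **base})
        treated = {k: v * r for (k, v), r in zip(base.items(), ratios)}
        rows.append({"plate": "P01", "well": "B01", "compound_id": "X",
                     **treated})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("ratios,expected", [
        ((1.0, 1.0, 1.0, 1.0), 1.0),
        ((2.0, 2.0, 2.0, 2.0), 2.0),
        ((1.5, 1.0, 2.0, 1.5), 1.5)])
    def test_composite_is_mean_of_dmso_ratios(self, ratios, expected):
        res = validation_score(self._paired(ratios))
        comp = res.scores.loc[res.scores.compound_id == "X", "composite"]
        assert comp.iloc[0] == pytest.approx(expected)

    def test_requires_three_dmso_wells(self):
        df = self._paired((1.0,) * 4)
        df = df[df.compound_id != "DMSO"].iloc[:1]
        with pytest.raises(ValueError):
            validation_score(pd.concat([df]))


class TestDoseResponse:
    DOSES = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)

    def test_strictly_increasing_gives_rho_one(self):
        df = pd.DataFrame({"dose_nm": self.DOSES,
                           "composite": [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]})
        res = dose_response(df)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["dose_dependent"]

    def test_constant_composites_flat(self):
        df = pd.DataFrame({"dose_nm": self.DOSES, "composite": [1.0] * 6})
        res = dose_response(df)
        assert res["spearman_rho"] == 0.0
        assert not res["dose_dependent"]

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        y = rng.normal(1.0, 0.1, 6)
        df = pd.DataFrame({"dose_nm": self.DOSES, "composite": y})
        res = dose_response(df)
        logd = np.log10(np.asarray(self.DOSES))
        obs = stats.spearmanr(logd, y).statistic
        count = total = 0
        for p in itertools.permutations(range(6)):
            total += 1
            if stats.spearmanr(logd, y[list(p)]).statistic >= obs - 1e-12:
                count += 1
        assert res["p_value"] == pytest.approx(count / total, abs=1e-12)

    def test_needs_three_dose_levels(self):
        df = pd.DataFrame({"dose_nm": [30.0, 100.0] * 3,
                           "composite": [1, 2, 3, 4, 5, 6.0]})
        with pytest.raises(ValueError):
            dose_response(df)


def test_full_screen_cascade_is_deterministic(screen_plates):
    a = score_screen(screen_plates)
    b = score_screen(screen_plates)
    assert a.zmatrix.equals(b.zmatrix)
    assert a.hits_pca == b.hits_pca
    assert a.hits_single_param == b.hits_single_param
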