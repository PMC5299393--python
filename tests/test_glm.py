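"""Tests of the first/second-level GLM machinery and cluster inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import ndimage, stats

from oscillofuse.config import CONDITIONS, NoiseConfig, SimConfig
from oscillofuse.glm import (
    NullRegressorError,
    RankDeficientError,
    bh_adjust,
    build_first_level_design,
    canonical_hrf,
    cluster_inference,
    fit_first_level_glm,
    label_clusters,
    orthogonalize_modulators,
    sample_regressor,
    second_level_contrast,
)
from oscillofuse.simulate import build_ground_truth, simulate_bold, simulate_task


class TestHRF:
    def test_zero_at_origin(self):
        h = canonical_hrf(2.0)
        assert h.values[0] == 0.0

    def test_mode_at_five_seconds_on_dense_grid(self):
        h = canonical_hrf(0.01, oversampling=1)
        assert abs(h.times[np.argmax(h.values)] - 5.0) <= 0.1

    def test_single_zero_crossing_after_mode(self):
        h = canonical_hrf(0.01, oversampling=1)
        tail = h.values[np.argmax(h.values):]
        signs = np.sign(tail[np.abs(tail) > 1e-12])
        assert np.sum(np.diff(signs) != 0) == 1

    def test_peak_normalized(self):
        assert canonical_hrf(2.0).values.max() == 1.0

    def test_matches_nilearn_spm_hrf_shape(self):
        # independent cross-check against the reference implementation
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = canonical_hrf(1.0, oversampling=16)
        theirs = nilearn_hrf.spm_hrf(1.0, oversampling=16)
        theirs = theirs / theirs.max()
        n = min(len(ours.values), len(theirs))
        r = np.corrcoef(ours.values[:n], theirs[:n])[0, 1]
        assert r > 0.999


class TestOrthogonalization:
    def _peaks(self, values, blocks=None, conditions=None):
        n = len(values)
        return pd.DataFrame(
            {
                "block": blocks if blocks is not None else [0] * n,
                "trial": np.arange(n),
                "condition": conditions if conditions is not None else ["large_gain"] * n,
                "peak_power": values,
            }
        )

    def test_constant_cell_gives_zero_weights(self):
        out = orthogonalize_modulators(self._peaks([2.0, 2.0, 2.0]))
        assert np.all(out["modulator_weight"] == 0.0)

    def test_arithmetic_example(self):
        out = orthogonalize_modulators(self._peaks([1.0, 2.0, 3.0]))
        assert np.allclose(out["modulator_weight"], [-1.0, 0.0, 1.0])

    def test_cell_means_exactly_zero(self):
        rng = np.random.default_rng(0)
        peaks = self._peaks(
            rng.exponential(2, 200),
            blocks=rng.integers(0, 4, 200),
            conditions=rng.choice(CONDITIONS, 200),
        )
        out = orthogonalize_modulators(peaks)
        cell_means = out.groupby(["block", "condition"])["modulator_weight"].mean()
        assert np.abs(cell_means).max() < 1e-12

    def test_single_trial_cell_weight_zero(self):
        out = orthogonalize_modulators(self._peaks([5.0]))
        assert out["modulator_weight"].iloc[0] == 0.0


def _balanced_trials(n_blocks=2, per_cond=6, pitch=10.0):
    rows = []
    for b in range(n_blocks):
        i = 0
        for rep in range(per_cond):
            for cond in CONDITIONS:
                t0 = 10.0 + i * pitch
                rows.append(
                    {
                        "subject": 0, "block": b, "trial": i,
                        "trial_onset": t0, "bold_onset": t0 + 2.0,
                        "feedback_onset": t0 + 4.0, "balance_onset": t0 + 6.0,
                        "response_onset": t0 + 0.5,
                        "magnitude": 25 if cond.startswith("large") else 5,
                        "valence": "loss" if cond.endswith("loss") else "gain",
                        "condition": cond, "response_made": True,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


class TestDesign:
    def test_530_scans_discard_5_gives_525_frames_per_block(self):
        trials = _balanced_trials(n_blocks=1, per_cond=6)
        X = build_first_level_design(trials, None, n_scans=530, tr=2.0, discard=5)
        assert X.matrix.shape[0] == 525
        assert X.frame_times[0] == 10.0  # first retained frame at 5 * TR

    def test_missing_condition_raises_null_regressor_error(self):
        trials = _balanced_trials(n_blocks=1, per_cond=6)
        trials = trials[trials["condition"] != "small_loss"]
        with pytest.raises(NullRegressorError, match="small_loss"):
            build_first_level_design(trials, None, n_scans=530, tr=2.0)

    def test_modulator_nearly_orthogonal_to_own_condition_regressor(self):
        trials = _balanced_trials(n_blocks=2, per_cond=6)
        rng = np.random.default_rng(1)
        weights = trials[["block", "trial", "condition"]].copy()
        weights["peak_power"] = rng.exponential(2.0, len(weights))
        weights = orthogonalize_modulators(weights)
        X = build_first_level_design(trials, weights, n_scans=140, tr=2.0)
        for cond in CONDITIONS:
            a = X.column(cond)
            b = X.column(f"mod_{cond}")
            r = np.corrcoef(a, b)[0, 1]
            assert abs(r) < 0.15

    def test_column_names_complete(self):
        trials = _balanced_trials(n_blocks=2, per_cond=3)
        motion = {b: np.zeros((140, 6)) for b in range(2)}
        motion = {b: np.cumsum(np.random.default_rng(b).normal(0, 0.01, (140, 6)), 0)
                  for b in range(2)}
        X = build_first_level_design(trials, None, n_scans=140, tr=2.0, motion=motion)
        for cond in CONDITIONS:
            assert cond in X.columns
        for name in ("stimulus", "response", "anticipation", "balance"):
            assert name in X.columns
        assert sum(c.startswith("motion_") for c in X.columns) == 6
        assert sum(c.endswith("intercept") for c in X.columns) == 2


class TestFirstLevel:
    def _design_and_data(self, n_vox=50, noise_sd=0.0, seed=0, ar=0.0):
        trials = _balanced_trials(n_blocks=1, per_cond=6)
        X = build_first_level_design(trials, None, n_scans=140, tr=2.0, discard=5)
        rng = np.random.default_rng(seed)
        true_betas = rng.normal(0, 1, (n_vox, X.matrix.shape[1]))
        Y_design = true_betas @ X.matrix.T
        full = np.zeros((n_vox, 140))
        full[:, 5:] = Y_design
        if noise_sd > 0:
            eps = rng.normal(0, noise_sd, (n_vox, 140))
            if ar > 0:
                for t in range(1, 140):
                    eps[:, t] += ar * eps[:, t - 1]
            full += eps
        return trials, X, full, true_betas

    def test_noiseless_recovery_to_1e8(self):
        _, X, Y, truth = self._design_and_data()
        res = fit_first_level_glm(Y, X, discard=5)
        scale = np.abs(truth).max()
        assert np.abs(res.betas - truth).max() / scale < 1e-8

    def test_residuals_orthogonal_to_design(self):
        _, X, Y, _ = self._design_and_data(noise_sd=1.0, seed=3)
        res = fit_first_level_glm(Y, X, discard=5)
        resid = Y[:, 5:] - res.betas @ X.matrix.T
        assert np.abs(X.matrix.T @ resid.T).max() < 1e-6

    def test_t_statistic_variance_matches_t_distribution(self):
        # null voxels: empirical var of t within 10% of df/(df-2)
        trials, X, _, _ = self._design_and_data(n_vox=2, noise_sd=1.0, seed=5)
        Y = np.zeros((2000, 140))
        Y[:, 5:] = np.random.default_rng(6).normal(0, 1.0, (2000, X.matrix.shape[0]))
        res = fit_first_level_glm(Y, X, discard=5)
        _, t = res.contrast({"large_gain": 1.0})
        expected = res.df / (res.df - 2)
        assert abs(np.var(t) - expected) / expected < 0.10

    def test_rank_deficient_design_reports_collinear_columns(self):
        trials = _balanced_trials(n_blocks=1, per_cond=6)
        X = build_first_level_design(trials, None, n_scans=140, tr=2.0)
        X.matrix = np.column_stack([X.matrix, X.matrix[:, 0]])
        X.columns = X.columns + ["dup"]
        with pytest.raises(RankDeficientError):
            fit_first_level_glm(np.zeros((3, 140)), X, discard=5)

    def test_prewhitening_estimates_ar_coefficient(self):
        _, X, Y, _ = self._design_and_data(n_vox=100, noise_sd=1.0, seed=7, ar=0.5)
        res = fit_first_level_glm(Y, X, prewhiten=True, discard=5)
        # lag-1 residual autocorrelation of AR(1) with phi=0.5 ~ 0.45-0.5
        assert 0.3 < np.median(res.ar_coefficient) < 0.6


class TestGammaRecovery:
    def test_gamma_theta_recovered_unbiased_over_replicates(self):
        """Coupling recovery: mean gamma estimate over the coupled cluster
        within 2 Monte-Carlo s.e. of the true 0.5 over 50 replicates."""
        n_rep = 50
        estimates = []
        for rep in range(n_rep):
            cfg = SimConfig(
                n_subjects=1, n_blocks=1, trials_per_block=40,
                eeg_sfreq=500.0, n_scans_per_block=210,
                grid_shape=(10, 10, 10), seed=40_000 + rep,
                coupling_theta_conditions=CONDITIONS,  # unconditional coupling
                noise=NoiseConfig(bold_sd=0.5, drift_amp=0.2),
            )
            trials = simulate_task(cfg)
            gt = build_ground_truth(trials, cfg)
            data = np.concatenate(simulate_bold(trials, gt, cfg), axis=3)
            weights = trials[["block", "trial", "condition"]].copy()
            weights["peak_power"] = gt.theta_power
            weights = orthogonalize_modulators(weights)
            X = build_first_level_design(
                trials, weights, n_scans=cfg.n_scans_per_block, tr=cfg.tr, discard=5
            )
            res = fit_first_level_glm(data, X, discard=5)
            # gamma estimate: average modulator beta over the coupled voxels
            mod_cols = [c for c in CONDITIONS if f"mod_{c}" in res.columns]
            mod = np.mean(
                [res.beta_map(f"mod_{c}")[gt.theta_coupled_mask] for c in mod_cols],
                axis=0,
            )
            scale = gt.subject_coupling_scale[0]
            estimates.append(mod.mean() / scale)
        estimates = np.array(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(n_rep)
        assert abs(estimates.mean() - 0.5) < 2 * mc_se


class TestSecondLevel:
    def _random_maps(self, n_sub=8, n_vox=64, seed=0):
        rng = np.random.default_rng(seed)
        return {
            s: {c: rng.normal(0, 1, n_vox) for c in CONDITIONS} for s in range(n_sub)
        }

    def test_equals_paired_t_on_two_condition_reduction(self):
        maps = self._random_maps()
        res = second_level_contrast(maps, {"large_gain": 1.0, "large_loss": -1.0})
        a = np.stack([maps[s]["large_gain"] for s in sorted(maps)])
        b = np.stack([maps[s]["large_loss"] for s in sorted(maps)])
        t_paired = stats.ttest_rel(a, b, axis=0).statistic
        assert np.abs(res.t_map - t_paired).max() < 1e-8

    def test_identical_maps_flagged_no_variance(self):
        m = np.ones(27)
        maps = {s: {c: m for c in CONDITIONS} for s in range(4)}
        res = second_level_contrast(maps, "gain_gt_loss")
        assert res.no_variance.all()
        assert np.all(res.t_map == 0.0)

    def test_missing_condition_names_subject(self):
        maps = self._random_maps(n_sub=3)
        del maps[1]["small_loss"]
        with pytest.raises(ValueError, match="small_loss"):
            second_level_contrast(maps, "gain_gt_loss")

    def test_null_rejection_rate_at_p001(self):
        # 500 null voxels, 12 subjects: rejections at p<0.001 within the
        # exact binomial band
        maps = self._random_maps(n_sub=12, n_vox=500, seed=9)
        res = second_level_contrast(maps, "gain_gt_loss")
        p = stats.t.sf(res.t_map, res.df)
        k = int((p < 0.001).sum())
        lo, hi = stats.binom.interval(0.95, 500, 0.001)
        assert lo <= k <= hi


class TestClusterInference:
    def _result_from_t(self, t_map_3d, n_sub=10, seed=0):
        # fabricate subject scores whose mean/sd reproduce the wanted t map
        rng = np.random.default_rng(seed)
        flat = t_map_3d.reshape(-1)
        scores = rng.normal(0, 1, (n_sub, flat.size))
        scores = scores - scores.mean(0)  # zero mean
        scores = scores / scores.std(0, ddof=1)  # unit sd
        scores = scores + flat / np.sqrt(n_sub)
        from oscillofuse.glm import SecondLevelResult

        mean = scores.mean(0)
        sd = scores.std(0, ddof=1)
        t = mean / (sd / np.sqrt(n_sub))
        return SecondLevelResult("test", scores, t, n_sub - 1,
                                 np.zeros(flat.size, dtype=bool))

    def test_extent_threshold_semantics_99_vs_101(self):
        shape = (20, 20, 20)
        t = np.zeros(shape)
        # cluster A: 99 voxels; cluster B: 101 voxels, both strongly supra
        t[1:12, 1:4, 1:4] = 50.0  # 11*3*3 = 99
        t[15:19, 5:10, 5:10] = 0.0
        flat_idx = np.argwhere(np.zeros(shape) == 0)
        b_vox = [(15, y, z) for y in range(5, 15) for z in range(5, 15)][:101]
        for v in b_vox:
            t[v] = 50.0
        res = self._result_from_t(t)
        table = cluster_inference(res, shape, voxel_p=0.001, extent_k=100,
                                  n_permutations=20, seed=1)
        assert len(table) == 1
        assert table.iloc[0]["size"] >= 100

    def test_labeling_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(2)

        def flood_fill(binary):
            # brute-force BFS with 26-neighbourhood
            out = np.zeros(binary.shape, dtype=int)
            lab = 0
            for start in np.argwhere(binary):
                if out[tuple(start)]:
                    continue
                lab += 1
                stack = [tuple(start)]
                out[tuple(start)] = lab
                while stack:
                    x, y, z = stack.pop()
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                if dx == dy == dz == 0:
                                    continue
                                p = (x + dx, y + dy, z + dz)
                                if all(0 <= p[i] < binary.shape[i] for i in range(3)):
                                    if binary[p] and not out[p]:
                                        out[p] = lab
                                        stack.append(p)
            return out, lab

        for _ in range(50):
            binary = rng.random((8, 8, 8)) < 0.2
            ours, n_ours = label_clusters(binary)
            oracle, n_oracle = flood_fill(binary)
            assert n_ours == n_oracle
            # same partition up to label permutation
            for lab in range(1, n_ours + 1):
                sel = ours == lab
                assert len(np.unique(oracle[sel])) == 1

    def test_all_zero_map_empty_table(self):
        res = self._result_from_t(np.zeros((6, 6, 6)))
        table = cluster_inference(res, (6, 6, 6), voxel_p=0.001, extent_k=1,
                                  n_permutations=10, seed=0)
        assert len(table) == 0

    def test_cluster_p_small_for_massive_effect(self):
        shape = (12, 12, 12)
        t = np.zeros(shape)
        t[2:8, 2:8, 2:8] = 30.0
        res = self._result_from_t(t, n_sub=12, seed=3)
        table = cluster_inference(res, shape, voxel_p=0.001, extent_k=10,
                                  n_permutations=200, seed=4)
        assert len(table) == 1
        assert table.iloc[0]["cluster_p"] < 0.05
        assert table.iloc[0]["cluster_q"] <= 1.0


class TestBH:
    def test_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)

        def oracle(p, m):
            # direct step-up definition: adj_(i) = min_{j>=i} (m/j) p_(j)
            order = np.argsort(p, kind="stable")
            k = len(p)
            adj = np.empty(k)
            for rank, idx in enumerate(order, start=1):
                best = min(
                    (m / j) * p[order[j - 1]] for j in range(rank, k + 1)
                )
                adj[idx] = min(1.0, best)
            return adj

        for _ in range(100):
            k = rng.integers(1, 20)
            p = rng.random(k)
            m = int(k + rng.integers(0, 10))
            assert np.allclose(bh_adjust(p, m=m), oracle(p, m))

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(12)
        p = rng.random(10)
        base = bh_adjust(p)
        for i in range(10):
            bumped = p.copy()
            bumped[i] = min(1.0, bumped[i] + 0.2)
            assert np.all(bh_adjust(bumped) >= base - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.1], m=1)

    @given(
        p=hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=30),
        extra=hst.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_step_up_properties_hold_for_arbitrary_inputs(self, p, extra):
        p = np.asarray(p)
        m = len(p) + extra
        adj = bh_adjust(p, m=m)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= p - 1e-15)  # adjustment never lowers a p
        # adjusted values preserve the raw-p ordering (step-up monotone)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
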