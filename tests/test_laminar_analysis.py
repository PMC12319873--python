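"""Vein exclusion, depth profiles, ADI, ocular ROIs, split-half."""

import numpy as np
import pandas as pd
import pytest

from dichopt.laminar import (
    adi_table,
    compute_adi,
    fit_block_glm,
    laminar_profile,
    select_ocular_rois,
    split_half_extract,
    surface_map,
    vein_mask,
)
from dichopt.synth.boldsim import LaminarTruth, make_odc_weights, simulate_bold_run


# ---------------------------------------------------------------------------
# Vein rule


class TestVeinMask:
    @pytest.fixture()
    def glm(self, noiseless_run):
        run = noiseless_run
        return run, fit_block_glm(run.bold, run.events, run.tr)

    def test_low_intensity_vertex_flagged(self, slab, glm):
        mesh, grid, _ = slab
        run, fit = glm
        target = grid.vertex_id[0]
        epi = fit.mean_epi.copy()
        epi[grid.vertex_id == target] *= 0.6  # 60 % of average intensity
        import dataclasses

        veins = vein_mask(dataclasses.replace(fit, mean_epi=epi), mesh, grid)
        assert veins.vertex_flagged[target]

    def test_high_response_vertex_flagged(self, slab, glm):
        mesh, grid, _ = slab
        run, fit = glm
        target = grid.vertex_id[0]
        beta = fit.beta.copy()
        beta[:, grid.vertex_id == target] = 12.0  # 12 PSC, normal intensity
        import dataclasses

        veins = vein_mask(dataclasses.replace(fit, beta=beta), mesh, grid)
        assert veins.vertex_flagged[target]

    def test_normal_vertex_kept_and_columns_whole(self, slab, glm):
        mesh, grid, _ = slab
        _, fit = glm
        veins = vein_mask(fit, mesh, grid)
        assert not veins.vertex_flagged.any()  # 5 PSC-scale betas, flat intensity
        # column completeness: a voxel is excluded iff its vertex is flagged
        assert np.array_equal(veins.voxel_keep, ~veins.vertex_flagged[grid.vertex_id])

    def test_planted_veins_detected_and_profile_restored(self, slab, events, hrf):
        mesh, grid, depth = slab
        rng = np.random.default_rng(3)
        vein_vertices = rng.choice(mesh.n_vertices, 12, replace=False)
        truth = LaminarTruth.from_adi(
            0.3, 1.0, vein_vertices=vein_vertices
        )
        weights = np.full((mesh.n_vertices, 2), 0.45)
        run = simulate_bold_run(
            mesh, grid, truth, events, tr=2.0, noise_sd=0.0, seed=1,
            weights=weights, hrf=hrf, depth=depth.depth,
        )
        fit = fit_block_glm(run.bold, events, 2.0, hrf=hrf)
        veins = vein_mask(fit, mesh, grid)
        flagged = np.flatnonzero(veins.vertex_flagged)
        sampled_veins = np.intersect1d(vein_vertices, np.unique(grid.vertex_id))
        assert np.isin(sampled_veins, flagged).all()
        # profile with exclusion recovers the planted FE amplitude
        prof = laminar_profile(fit, depth, mask=veins, n_bins=3)
        assert np.abs(prof["FE"].to_numpy() - 0.45).max() < 1e-6
        # without exclusion the vein amplification inflates the profile
        prof_raw = laminar_profile(fit, depth, mask=None, n_bins=3)
        assert prof_raw["FE"].max() > prof["FE"].max() + 0.05

    def test_everything_flagged_rejected(self, slab, glm):
        mesh, grid, _ = slab
        _, fit = glm
        import dataclasses

        hot = dataclasses.replace(fit, beta=np.full_like(fit.beta, 50.0))
        with pytest.raises(ValueError, match="every vertex"):
            vein_mask(hot, mesh, grid)


# ---------------------------------------------------------------------------
# Profiles and ADI


class TestProfilesADI:
    def test_uniform_beta_flat_profile(self, noiseless_run, slab):
        _, _, depth = slab
        run = noiseless_run
        glm = fit_block_glm(run.bold, run.events, run.tr)
        prof = laminar_profile(glm, depth, n_bins=3)
        # FE truth is flat 1.0 with weight 0.45 -> flat 0.45
        assert np.abs(prof["FE"].to_numpy() - 0.45).max() < 1e-6
        assert (prof["n_voxels"] > 0).all()

    def test_empty_bin_is_nan_not_zero(self, noiseless_run, slab):
        _, _, depth = slab
        run = noiseless_run
        glm = fit_block_glm(run.bold, run.events, run.tr)
        prof = laminar_profile(glm, depth, n_bins=50)
        empty = prof["n_voxels"] == 0
        if empty.any():
            assert prof.loc[empty, "FE"].isna().all()

    def test_adi_arithmetic(self):
        assert compute_adi([0.5], [1.0])[0] == pytest.approx(0.5)
        assert compute_adi([0.8], [0.8])[0] == pytest.approx(0.0)
        assert np.isnan(compute_adi([0.5], [0.0])[0])
        assert np.isnan(compute_adi([0.5], [-0.2])[0])

    def test_adi_scale_invariance(self):
        """Pure feedforward scaling: ADI invariant to any positive gain."""
        ae = np.array([0.4, 0.5, 0.6])
        fe = np.array([0.8, 0.9, 1.0])
        for gain in (0.1, 3.7, 250.0):
            assert np.allclose(compute_adi(gain * ae, gain * fe), compute_adi(ae, fe))

    def test_flat_planted_adi_recovered_flat(self, noiseless_run, slab):
        """Feedforward deficit: flat ADI 0.3 across all three layers."""
        _, _, depth = slab
        run = noiseless_run
        glm = fit_block_glm(run.bold, run.events, run.tr)
        adi = adi_table(laminar_profile(glm, depth, n_bins=3))["adi"].to_numpy()
        assert np.abs(adi - 0.3).max() < 1e-6

    def test_planted_superficial_bias_is_monotone(self, slab, events, hrf):
        mesh, grid, depth = slab
        truth = LaminarTruth(
            depth_grid=np.linspace(0, 1, 21),
            profile_ae=np.linspace(1.5, 0.5, 21),
            profile_fe=np.linspace(1.5, 0.5, 21),
            bsi_ae=0.0,
            bsi_fe=0.0,
        )
        w = np.full((mesh.n_vertices, 2), 0.45)
        run = simulate_bold_run(
            mesh, grid, truth, events, tr=2.0, noise_sd=0.0, seed=0,
            weights=w, hrf=hrf, depth=depth.depth,
        )
        glm = fit_block_glm(run.bold, events, 2.0, hrf=hrf)
        prof = laminar_profile(glm, depth, n_bins=3)["FE"].to_numpy()
        assert prof[0] > prof[1] > prof[2]  # increases toward the pial surface


# ---------------------------------------------------------------------------
# Ocular-bias ROIs


class TestOcularROIs:
    def test_exact_count_per_side(self):
        rng = np.random.default_rng(0)
        ae, fe = rng.standard_normal((2, 1000))
        rois = select_ocular_rois(ae, fe, frac=0.10)
        assert len(rois["AE_biased"]) == len(rois["FE_biased"]) == 100
        assert not np.intersect1d(rois["AE_biased"], rois["FE_biased"]).size

    def test_antisymmetric_map_mirrors(self):
        diff = np.linspace(-1, 1, 200)
        rois = select_ocular_rois(diff, np.zeros_like(diff), frac=0.1)
        assert np.array_equal(rois["AE_biased"], 199 - rois["FE_biased"][::-1])

    def test_frac_too_small_rejected(self):
        with pytest.raises(ValueError):
            select_ocular_rois(np.arange(4.0), np.zeros(4), frac=0.1)
        with pytest.raises(ValueError):
            select_ocular_rois(np.arange(10.0), np.zeros(10), frac=0.7)

    def test_selected_vertices_match_true_preference(self, slab, events, hrf):
        """With ODC-patterned weights and modest noise, >= 95 % of selected
        vertices have the matching planted ocular preference."""
        mesh, grid, depth = slab
        truth = LaminarTruth.from_adi(0.0, 1.0)
        weights = make_odc_weights(mesh, contrast=0.9, gain=0.9, seed=4)
        run = simulate_bold_run(
            mesh, grid, truth, events, tr=2.0, noise_sd=0.1, seed=7,
            weights=weights, hrf=hrf, depth=depth.depth,
        )
        glm = fit_block_glm(run.bold, events, 2.0, hrf=hrf)
        ae_map = surface_map(glm.beta_for("AE"), grid, mesh.n_vertices)
        fe_map = surface_map(glm.beta_for("FE"), grid, mesh.n_vertices)
        ok = ~np.isnan(ae_map)
        idx = np.flatnonzero(ok)
        rois = select_ocular_rois(ae_map[ok], fe_map[ok], frac=0.10)
        true_pref = weights[:, 0] - weights[:, 1]
        ae_sel = idx[rois["AE_biased"]]
        fe_sel = idx[rois["FE_biased"]]
        assert (true_pref[ae_sel] > 0).mean() >= 0.95
        assert (true_pref[fe_sel] < 0).mean() >= 0.95


# ---------------------------------------------------------------------------
# Split-half


class TestSplitHalf:
    conditions = ["AE", "FE", "binocular"]

    def test_identical_runs_equal_single_run(self):
        rng = np.random.default_rng(1)
        one = rng.standard_normal((3, 500))
        maps = np.stack([one, one, one, one])
        out = split_half_extract(maps, self.conditions)
        rois = select_ocular_rois(one[0], one[1], 0.1)
        direct = {
            roi: one[:, v].mean(axis=1) for roi, v in rois.items()
        }
        for roi in direct:
            assert np.allclose(out.loc[roi].to_numpy(), direct[roi])

    def test_swapped_halves_same_average(self):
        rng = np.random.default_rng(2)
        maps = rng.standard_normal((4, 3, 300))
        a = split_half_extract(maps, self.conditions)
        swapped = maps[[1, 0, 3, 2]]
        b = split_half_extract(swapped, self.conditions)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            split_half_extract(np.zeros((1, 3, 100)), self.conditions)

    def test_no_selection_bias_inflation(self):
        """Independent noise halves: the extracted AE-FE contrast is an
        unbiased estimate of the true contrast (circular analysis would
        inflate it)."""
        rng = np.random.default_rng(5)
        n_v = 400
        true_ae = np.zeros(n_v)  # no true ocular bias anywhere
        errs_split, errs_circular = [], []
        for _ in range(100):
            maps = 0.5 + np.zeros((4, 3, n_v))
            maps += rng.standard_normal((4, 3, n_v)) * 0.5
            out = split_half_extract(maps, self.conditions, frac=0.1)
            errs_split.append(out.loc["AE_biased", "AE"] - out.loc["AE_biased", "FE"])
            mean_map = maps.mean(axis=0)
            rois = select_ocular_rois(mean_map[0], mean_map[1], 0.1)
            sel = mean_map[:, rois["AE_biased"]].mean(axis=1)
            errs_circular.append(sel[0] - sel[1])
        errs_split = np.array(errs_split)
        ci = 3 * errs_split.std(ddof=1) / 10
        assert abs(errs_split.mean()) < ci  # unbiased
        assert np.mean(errs_circular) > 5 * ci  # the circular estimate is not
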