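"""Searchlight geometry, neural RDMs, and Spearman similarity maps."""

import numpy as np
import pytest

from conftest import brute_force_corr_rdm, rank_average, spearman_oracle
from slrsa import glm, rdm, searchlight, studies, synth


def _beta_set(patterns, mask, concepts=None):
    if concepts is None:
        concepts = [f"c{i:02d}" for i in range(patterns.shape[0])]
    return glm.TrialBetaSet(concepts=concepts, betas=patterns, mask=mask)


class TestSphereGeometry:
    def test_radius_three_sphere_has_123_voxels(self):
        # independent offset-enumeration oracle
        count = sum(
            1
            for dx in range(-3, 4)
            for dy in range(-3, 4)
            for dz in range(-3, 4)
            if dx * dx + dy * dy + dz * dz <= 9
        )
        assert count == 123
        assert len(searchlight.sphere_offsets(3.0)) == count

    def test_deep_center_neighborhood_size_in_solid_mask(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        sls = searchlight.searchlight_centers(mask, 3.0, 0.5)
        center_idx = [i for i, c in enumerate(sls.centers)
                      if tuple(c) == (4, 4, 4)]
        assert len(center_idx) == 1
        assert len(sls.neighbors[center_idx[0]]) == 123

    def test_boundary_centers_below_min_fraction_excluded(self):
        # a center on the face of a half-space mask has ~50% coverage;
        # a corner voxel has ~1/8 and must be excluded at min_fraction 0.5
        mask = np.ones((10, 10, 10), dtype=bool)
        sls = searchlight.searchlight_centers(mask, 3.0, 0.5)
        retained = {tuple(c) for c in sls.centers}
        assert (0, 0, 0) not in retained
        assert (5, 5, 5) in retained

    def test_small_radius_gives_singleton_neighborhoods(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        sls = searchlight.searchlight_centers(mask, 0.5, 0.5)
        assert all(len(n) == 1 for n in sls.neighbors)
        assert sls.n_centers == 64

    def test_every_neighborhood_contains_its_center(self, small_mask):
        sls = searchlight.searchlight_centers(small_mask, 3.0, 0.5)
        vox_index = np.full(small_mask.shape, -1, dtype=int)
        vox_index[small_mask] = np.arange(small_mask.sum())
        for c, nbrs in zip(sls.centers, sls.neighbors):
            assert vox_index[tuple(c)] in nbrs


class TestNeuralRdm:
    def test_identical_patterns_have_zero_distance(self):
        mask = np.ones((2, 2, 3), dtype=bool)
        p = np.vstack([np.arange(12.0), np.arange(12.0),
                       np.random.default_rng(0).standard_normal(12)])
        out = searchlight.neural_rdm(_beta_set(p, mask), np.arange(12))
        assert out.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        mask = np.ones((2, 5, 2), dtype=bool)
        p = rng.standard_normal((4, 20))
        idx = np.array([0, 2, 3, 5, 7, 8, 11, 13, 17, 19])
        out = searchlight.neural_rdm(_beta_set(p, mask), idx)
        assert np.abs(out.d - brute_force_corr_rdm(p[:, idx])).max() < 1e-12

    def test_constant_pattern_flagged(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        p = np.vstack([np.ones(8), np.arange(8.0)])
        with pytest.raises(searchlight.ConstantPatternError):
            searchlight.neural_rdm(_beta_set(p, mask), np.arange(8))


class TestRsaMap:
    def _planted_setup(self, noise_sd, seed=0):
        shape = (14, 14, 14)
        mask = synth.ellipsoid_mask(shape)
        roi = synth.ball_roi(mask, (6.5, 6.5, 6.5), 250)
        target = synth.grouped_rdm(12)
        sls = searchlight.searchlight_centers(mask, 3.0, 0.5)
        pat = synth.embed_geometry(target, roi.size, roi, amplitude=10.0,
                                   seed=seed)
        base = synth.make_event_design({"word": 12, "pseudoword": 12},
                                       seed=seed)
        design = synth.assign_stimuli(base, "word", sorted(target.labels),
                                      seed=seed)
        vol = synth.simulate_bold(design, pat, shape=shape, mask=mask,
                                  noise_sd=noise_sd, seed=seed + 1)
        betas = glm.lss_betas(vol, design, ar1=False)
        return betas, target, sls, mask, roi

    def test_values_match_per_center_compare_rdms(self):
        betas, target, sls, mask, _ = self._planted_setup(noise_sd=1.0)
        out = searchlight.rsa_map(betas, target, sls)
        for i in range(0, sls.n_centers, 97):  # spot-check centers
            nr = searchlight.neural_rdm(betas, sls.neighbors[i])
            expected = rdm.compare_rdms(nr, target).rho
            got = out.values[tuple(sls.centers[i])]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_null_searchlights_average_near_zero(self):
        # ROI sits at one end of an elongated grid, so hundreds of
        # searchlights contain no signal voxel at all
        shape = (24, 16, 16)
        mask, roi, _ = studies._recovery_geometry(shape)
        space = synth.make_semantic_space(16, 50, n_latent=4, noise_sd=0.5,
                                         seed=7)
        target = rdm.correlation_distance_rdm(space.vectors,
                                              labels=space.concepts)
        sls = searchlight.searchlight_centers(mask, 3.0, 0.5)
        roi_flat = np.zeros(mask.size, dtype=bool)
        roi_flat[roi] = True
        in_cols = np.flatnonzero(mask.reshape(-1))
        null_centers = [
            tuple(c) for c, nbrs in zip(sls.centers, sls.neighbors)
            if not roi_flat[in_cols[nbrs]].any()
        ]
        assert len(null_centers) >= 200
        # overlapping spheres share noise, so per-searchlight values are
        # dependent; replicate over independent subjects and use the
        # across-subject standard error of the null-region mean
        subject_means = []
        for seed in range(10):
            values = studies.recovery_single_subject(
                3000 + 7 * seed, target, mask, roi, sls, shape)
            subject_means.append(
                np.nanmean([values[c] for c in null_centers]))
        subject_means = np.array(subject_means)
        se = subject_means.std(ddof=1) / np.sqrt(subject_means.size)
        assert abs(subject_means.mean()) < 3 * se

    def test_label_mismatch_rejected(self):
        betas, target, sls, _, _ = self._planted_setup(noise_sd=0.5)
        other = rdm.RDM(labels=[f"x{i}" for i in range(12)],
                        d=np.asarray(target.d))
        with pytest.raises(ValueError, match="labels"):
            searchlight.rsa_map(betas, other, sls)

    def test_invariant_under_common_concept_reordering(self):
        betas, target, sls, mask, _ = self._planted_setup(noise_sd=1.0)
        out = searchlight.rsa_map(betas, target, sls)
        perm = np.random.default_rng(4).permutation(12)
        betas2 = glm.TrialBetaSet(
            concepts=[betas.concepts[i] for i in perm],
            betas=betas.betas[perm], mask=mask)
        target2 = rdm.RDM(labels=[target.labels[i] for i in perm],
                          d=np.asarray(target.d)[np.ix_(perm, perm)])
        out2 = searchlight.rsa_map(betas2, target2, sls)
        assert np.allclose(out.values, out2.values, atol=1e-10,
                           equal_nan=True)

    def test_planted_identity_and_spatial_specificity(self):
        """Zero-noise planted geometry: rho = 1 at ROI-interior centers and
        high-rho centers stay within the dilated ROI."""
        res = studies.planted_identity_study(seed=1, n_conditions=12,
                                             roi_size=250, shape=(14, 14, 14))
        assert res["max_abs_dev"] < 1e-6
        # spatial specificity: recompute the map and check rho > 0.9 only
        # near the ROI
        shape = (14, 14, 14)
        mask = synth.ellipsoid_mask(shape)
        roi = synth.ball_roi(mask, [s / 2 for s in shape], 250)
        roi_grid = np.zeros(mask.size, dtype=bool)
        roi_grid[roi] = True
        roi_grid = roi_grid.reshape(shape)
        from scipy import ndimage
        dilated = ndimage.binary_dilation(
            roi_grid, iterations=3,
            structure=ndimage.generate_binary_structure(3, 3))
        target = synth.grouped_rdm(12)
        pat = synth.embed_geometry(target, roi.size, roi, amplitude=2.0,
                                   seed=1)
        design = studies._spaced_design(12, sorted(target.labels))
        vol = synth.simulate_bold(design, pat, shape=shape, mask=mask,
                                  noise_sd=0.0, seed=2)
        betas = glm.lss_betas(vol, design, ar1=False, hpf_cutoff_s=None)
        sls = searchlight.searchlight_centers(mask, 3.0, 0.5)
        out = searchlight.rsa_map(betas, target, sls)
        high = np.argwhere(np.nan_to_num(out.values, nan=0.0) > 0.9)
        assert high.size > 0
        assert all(dilated[tuple(ijk)] for ijk in high)

    def test_mean_roi_rho_decreases_with_noise(self):
        """More scanner noise means worse model-brain correspondence."""
        shape = (24, 16, 16)
        mask, roi, _ = studies._recovery_geometry(shape)
        space = synth.make_semantic_space(16, 50, n_latent=4, noise_sd=0.5,
                                         seed=7)
        target = rdm.correlation_distance_rdm(space.vectors,
                                              labels=space.concepts)
        sls = searchlight.searchlight_centers(mask, 3.0, 0.5)
        roi_mask = np.zeros(mask.size, dtype=bool)
        roi_mask[roi] = True
        centers_flat = np.ravel_multi_index(sls.centers.T, shape)
        in_roi = roi_mask[centers_flat]
        means = []
        for noise_sd in (0.5, 1.0, 2.0):
            vals = []
            for seed in range(20):
                m = studies.recovery_single_subject(
                    1000 + seed, target, mask, roi, sls, shape,
                    noise_sd=noise_sd)
                vals.append(np.nanmean(m[tuple(sls.centers[in_roi].T)]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPartialRsaMap:
    def _setup(self):
        rng = np.random.default_rng(6)
        mask = np.ones((6, 6, 6), dtype=bool)
        betas = _beta_set(rng.standard_normal((6, 216)), mask,
                          concepts=list("abcdef"))
        model = rdm.correlation_distance_rdm(rng.standard_normal((6, 30)),
                                             labels=list("abcdef"))
        nuis = rdm.correlation_distance_rdm(rng.standard_normal((6, 30)),
                                            labels=list("abcdef"))
        sls = searchlight.searchlight_centers(mask, 2.0, 0.3)
        return betas, model, nuis, sls

    def test_empty_nuisance_equals_rsa_map(self):
        betas, model, _, sls = self._setup()
        a = searchlight.rsa_map(betas, model, sls)
        b = searchlight.partial_rsa_map(betas, model, [], sls)
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_nuisance_copy_of_model_rejected(self):
        betas, model, _, sls = self._setup()
        with pytest.raises(ValueError, match="collinear"):
            searchlight.partial_rsa_map(betas, model, [model], sls)

    def test_matches_residualization_oracle(self):
        betas, model, nuis, sls = self._setup()
        out = searchlight.partial_rsa_map(betas, model, [nuis], sls)
        # oracle: rank everything, regress out nuisance ranks, correlate
        i = 17
        nr_cells = searchlight.neural_rdm(betas, sls.neighbors[i]).cells()

        def resid(v, z):
            zz = np.column_stack([np.ones(v.size), z])
            coef, *_ = np.linalg.lstsq(zz, v, rcond=None)
            return v - zz @ coef

        rn = rank_average(nr_cells)
        rm = rank_average(model.cells())
        rz = rank_average(nuis.cells())
        en, em = resid(rn, rz), resid(rm, rz)
        expected = (en @ em) / np.sqrt((en @ en) * (em @ em))
        got = out.values[tuple(sls.centers[i])]
        assert got == pytest.approx(expected, abs=1e-10)
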