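"""Canonical verification studies run on synthetic data.

Each function sets up one fixed, documented study condition — a planted
representational geometry, a solver-equivalence check, a null calibration,
or a parameter-recovery experiment — runs the pipeline on it, and returns
the measured quantities.  The test suite and the acceptance script both
call these functions so that the verified conditions are defined in
exactly one place.
"""

from __future__ import annotations

import numpy as np

from . import glm, inference, rdm, searchlight, synth

__all__ = [
    "planted_identity_study",
    "lss_ols_oracle_study",
    "fwe_calibration_study",
    "recovery_study",
    "RECOVERY_AMPLITUDE",
    "RECOVERY_NOISE_SD",
]

#: pattern amplitude and noise level of the moderate-noise recovery study,
#: calibrated once so a single subject's mean ROI searchlight rho is ~0.2
RECOVERY_AMPLITUDE = 10.0
RECOVERY_NOISE_SD = 1.0
#: lag-1 autocorrelation of the simulated scanner noise
RECOVERY_AR1 = 0.3


def _spaced_design(n_trials: int, labels, tr: float = 2.0,
                   spacing_s: float = 36.0) -> synth.EventDesign:
    """Event design with trials separated beyond the HRF support.

    With 36 s between onsets the HRF responses of different trials do not
    overlap, which makes trial-wise least squares estimates exact on
    noise-free data.
    """
    onsets = 4 * tr + np.arange(n_trials) * spacing_s
    return synth.EventDesign(
        onsets=onsets,
        durations=np.full(n_trials, 2.4),
        conditions=np.array(list(labels), dtype=object),
        run_length=float(onsets[-1] + spacing_s),
        tr=tr,
    )


def planted_identity_study(seed: int = 0, n_conditions: int = 58,
                           roi_size: int = 300, shape=(18, 18, 18)) -> dict:
    """End-to-end identity: planted RDM -> BOLD -> LSS -> searchlight.

    A block-structured RDM over ``n_conditions`` concepts is planted
    exactly in a compact ROI; the noise-free BOLD series is estimated with
    trial-wise least squares and swept with radius-3 searchlights.  At
    every searchlight lying entirely inside the ROI the Spearman
    correlation with the planted RDM must be 1.  Returns the worst
    deviation from 1 over those interior searchlights.
    """
    mask = synth.ellipsoid_mask(shape)
    roi = synth.ball_roi(mask, [s / 2 for s in shape], roi_size)
    # two groups: the RDM has exactly two cell levels (within 0, between
    # 1 - corr), whose order is preserved under any voxel subsampling, so
    # the identity is exact for every seed; graded multi-group targets are
    # exercised separately at module level
    target = synth.grouped_rdm(n_conditions, n_groups=2)
    pat = synth.embed_geometry(target, roi.size, roi, amplitude=2.0,
                               seed=seed)
    design = _spaced_design(n_conditions, sorted(target.labels))
    vol = synth.simulate_bold(design, pat, shape=shape, mask=mask,
                              noise_sd=0.0, seed=seed + 1)
    betas = glm.lss_betas(vol, design, ar1=False, hpf_cutoff_s=None)
    sls = searchlight.searchlight_centers(mask, radius_vox=3.0,
                                          min_fraction=0.5)
    rho = searchlight.rsa_map(betas, target, sls)
    roi_flat = np.zeros(mask.size, dtype=bool)
    roi_flat[pat.roi_indices] = True
    in_cols = np.flatnonzero(mask.reshape(-1))
    devs = []
    for center, nbrs in zip(sls.centers, sls.neighbors):
        if roi_flat[in_cols[nbrs]].all():
            devs.append(abs(1.0 - rho.values[tuple(center)]))
    if not devs:
        raise RuntimeError("no searchlight lies entirely inside the ROI")
    return {
        "max_abs_dev": float(max(devs)),
        "n_interior": len(devs),
        "min_rho": float(1.0 - max(devs)),
    }


def lss_ols_oracle_study(seed: int = 0, n_words: int = 64,
                         n_voxels: int = 500) -> dict:
    """Trial-wise LSS betas against an independent normal-equations oracle.

    A 64-word + 64-pseudoword jittered design is simulated with planted
    patterns and noise; each trial's three-regressor model is then solved
    twice — by the package's estimator and by directly solving the normal
    equations ``(X'X) b = X'y`` — and the largest absolute coefficient
    difference is reported.
    """
    shape = (10, 10, 5)  # 500 voxels, all in mask
    mask = np.ones(shape, dtype=bool)
    labels = [f"word_{i:03d}" for i in range(n_words)]
    base = synth.make_event_design({"word": n_words, "pseudoword": n_words},
                                   seed=seed)
    design = synth.assign_stimuli(base, "word", labels, seed=seed + 1)
    target = synth.grouped_rdm(n_words, labels=labels)
    roi = np.arange(n_voxels)
    pat = synth.embed_geometry(target, n_voxels, roi, amplitude=5.0,
                               seed=seed + 2)
    vol = synth.simulate_bold(design, pat, shape=shape, mask=mask,
                              noise_sd=1.0, ar1_phi=0.0, seed=seed + 3)
    betas = glm.lss_betas(vol, design, ar1=False, hpf_cutoff_s=128.0)

    # independent oracle: rebuild each trial's design and solve X'X b = X'y
    y = vol.data[mask].T
    n_vols = y.shape[0]
    tr = vol.tr
    word_cols = glm.task_regressors(design, sorted(labels), n_vols, tr)
    pseudo = glm.task_regressors(design, ["pseudoword"], n_vols, tr)
    drifts = glm.dct_drifts(n_vols, tr, 128.0)
    const = np.ones((n_vols, 1))
    max_diff = 0.0
    for i, lab in enumerate(sorted(labels)):
        target_col = word_cols[:, i : i + 1]
        others = word_cols.sum(axis=1, keepdims=True) - target_col
        x = np.column_stack([target_col, others, pseudo, drifts, const])
        b = np.linalg.solve(x.T @ x, x.T @ y)
        max_diff = max(max_diff, float(np.abs(b[0] - betas.betas[i]).max()))
    return {"max_abs_diff": max_diff, "n_trials": n_words,
            "n_voxels": n_voxels}


def _exact_mask(n_voxels: int = 2000, shape=(20, 17, 17)) -> np.ndarray:
    """Compact mask with exactly ``n_voxels`` in-mask voxels."""
    base = synth.ellipsoid_mask(shape, semiaxes=[0.48 * s for s in shape])
    idx = synth.ball_roi(base, [(s - 1) / 2 for s in shape], n_voxels)
    mask = np.zeros(shape, dtype=bool)
    mask.reshape(-1)[idx] = True
    return mask


def fwe_calibration_study(seed: int = 0, n_datasets: int = 200,
                          n_subjects: int = 12, n_voxels: int = 2000,
                          n_perm: int = 500, smooth_fwhm_vox: float = 2.0,
                          cluster_alpha: float = 0.05) -> dict:
    """Family-wise error calibration of cluster inference under the null.

    ``n_datasets`` independent datasets of ``n_subjects`` null Gaussian
    maps over ``n_voxels`` in-mask voxels are each submitted to sign-flip
    cluster inference; the fraction of datasets with at least one
    significant cluster estimates the family-wise error rate, which should
    match ``cluster_alpha``.

    The null maps are Gaussian random fields smoothed to ``smooth_fwhm_vox``
    voxels FWHM, matching the smoothness searchlight maps inherit from
    overlapping spheres.  On completely unsmoothed i.i.d. noise the maximum
    cluster size takes only a handful of values and the (valid) permutation
    test becomes markedly conservative through discreteness, which would
    measure the statistic's granularity rather than the procedure's
    calibration.
    """
    mask = _exact_mask(n_voxels)
    root = np.random.default_rng(seed)
    n_any = 0
    for _ in range(n_datasets):
        ds_seed = int(root.integers(2**31))
        rng = np.random.default_rng(ds_seed)
        maps = np.array([
            glm.smooth_volume(rng.standard_normal(mask.shape),
                              smooth_fwhm_vox, (1.0, 1.0, 1.0))[mask]
            for _ in range(n_subjects)
        ])
        gs = inference.GroupSample(maps=maps, mask=mask)
        res = inference.cluster_inference(
            gs, mode="one_sample", voxel_p=0.001,
            cluster_alpha=cluster_alpha, n_perm=n_perm,
            seed=int(root.integers(2**31)),
        )
        n_any += res.sig_mask.any()
    return {"fwe_rate": n_any / n_datasets, "n_datasets": n_datasets,
            "n_perm": n_perm}


def _recovery_geometry(shape=(24, 16, 16), roi_size: int = 300):
    mask = synth.ellipsoid_mask(shape)
    roi = synth.ball_roi(mask, (6.0, 7.5, 7.5), roi_size)
    ctrl = synth.ball_roi(mask, (17.5, 7.5, 7.5), roi_size)
    return mask, roi, ctrl


def recovery_single_subject(seed: int, target: rdm.RDM, mask, roi, sls,
                            shape, noise_sd: float = RECOVERY_NOISE_SD
                            ) -> np.ndarray:
    """One synthetic subject's searchlight map under the recovery study."""
    concepts = list(target.labels)
    pat = synth.embed_geometry(target, roi.size, roi,
                               amplitude=RECOVERY_AMPLITUDE, seed=seed)
    base = synth.make_event_design(
        {"word": len(concepts), "pseudoword": len(concepts)}, seed=seed)
    design = synth.assign_stimuli(base, "word", concepts, seed=seed + 1)
    vol = synth.simulate_bold(design, pat, shape=shape, mask=mask,
                              noise_sd=noise_sd,
                              ar1_phi=RECOVERY_AR1, seed=seed + 2)
    betas = glm.lss_betas(vol, design, ar1=True)
    return searchlight.rsa_map(betas, target, sls).values


def recovery_study(seed: int = 0, n_seeds: int = 20, n_subjects: int = 12,
                   n_concepts: int = 16, n_perm: int = 199) -> dict:
    """Parameter recovery under moderate noise.

    A 16-concept correlation-distance RDM (from a latent-factor semantic
    space) is planted in a 300-voxel ROI at an amplitude/noise ratio giving
    single-subject ROI rho of about 0.2; for each of ``n_seeds`` replicate
    studies, ``n_subjects`` synthetic subjects are simulated, estimated and
    searchlight-mapped, and one-sample sign-flip cluster inference is run.
    Reports the fraction of replicates with a significant cluster
    intersecting the ROI (power) and the fraction with any significant
    cluster inside a disjoint control region (false positives), plus the
    mean single-subject ROI rho actually realized.
    """
    shape = (24, 16, 16)
    mask, roi, ctrl = _recovery_geometry(shape)
    space = synth.make_semantic_space(n_concepts, 50, n_latent=4,
                                     noise_sd=0.5, seed=7)
    target = rdm.correlation_distance_rdm(space.vectors,
                                          labels=space.concepts)
    sls = searchlight.searchlight_centers(mask, radius_vox=3.0,
                                          min_fraction=0.5)
    roi_mask = np.zeros(shape, dtype=bool)
    roi_mask.reshape(-1)[roi] = True
    ctrl_mask = np.zeros(shape, dtype=bool)
    ctrl_mask.reshape(-1)[ctrl] = True
    centers_flat = np.ravel_multi_index(sls.centers.T, shape)
    in_roi_center = roi_mask.reshape(-1)[centers_flat]

    root = np.random.default_rng(seed)
    hits = 0
    false_pos = 0
    subj_rhos = []
    for _ in range(n_seeds):
        stack = np.full(shape + (n_subjects,), np.nan)
        for s in range(n_subjects):
            ss = int(root.integers(2**31 - 10))
            stack[..., s] = recovery_single_subject(ss, target, mask, roi,
                                                    sls, shape)
            subj_rhos.append(np.nanmean(
                stack[..., s][tuple(sls.centers[in_roi_center].T)]))
        gs = inference.GroupSample.from_stack(stack, mask)
        res = inference.cluster_inference(
            gs, mode="one_sample", voxel_p=0.001, cluster_alpha=0.05,
            n_perm=n_perm, seed=int(root.integers(2**31)),
        )
        hits += bool((res.sig_mask & roi_mask).any())
        false_pos += bool((res.sig_mask & ctrl_mask).any())
    return {
        "hit_rate": hits / n_seeds,
        "control_fp_rate": false_pos / n_seeds,
        "mean_subject_roi_rho": float(np.mean(subj_rhos)),
        "n_seeds": n_seeds,
    }
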