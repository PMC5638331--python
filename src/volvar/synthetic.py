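"""Synthetic cohort and phantom-image generation.

The generator emulates the *measurement structure* of a scan-rescan
volumetry study — participant × scan × run × pre-processing step × ROI —
without simulating image intensities or registrations. Volumes are
multiplicative log-normal so that they stay positive and errors scale with
region size:

    TBV_i            = tbv_mean * LN((tbv_sd/tbv_mean)^2)
    TBV record (i,j) = TBV_i * tbv_step_bias_j
    V_{i,k,m,j,r}    = TBV_i * base_ratio_r
                       * LN(subject_sd^2)        # per (i, r)
                       * step_bias_{j,r}
                       * LN(scan_noise_sd_{j,r}^2)  # per scan k
                       * LN(run_noise_sd_j^2)       # per run m

where LN(s^2) = exp(N(-s^2/2, s^2)) is *mean-one* log-normal noise. The
mean-one location shift matters: plain exp(N(0, s^2)) has expectation
exp(s^2/2), so noise sigmas that differ by step would bias expected volumes
differently per step and a config with equal step biases would not be a
true null. With mean-one noise, expected volumes depend on the biases only.

Scan noise is drawn once per scan and shared by all runs of that scan; run
noise is drawn per pipeline run. A single root seed drives per-axis
substreams, so the same config and seed reproduce a bit-identical table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .images import LabelImage

__all__ = ["generate_volume_table", "generate_label_image", "perturb_label_image"]


def generate_volume_table(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the long-format measurement table for a synthetic cohort.

    Returns a DataFrame with one record per (participant, scan, run, step,
    ROI) and columns ``participant_id, scan_index, run_index, step, roi,
    volume_mm3, tbv_mm3``. ``seed`` overrides ``config.seed`` when given.
    """
    P, K, M = config.n_participants, config.n_scans, config.n_runs
    steps, rois = list(config.steps), list(config.rois)
    J, R = len(steps), len(rois)

    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_tbv, rng_subj, rng_scan, rng_run = (np.random.default_rng(s) for s in root.spawn(4))

    def mean_one_lognormal(z: np.ndarray, sigma) -> np.ndarray:
        # exp(N(-sigma^2/2, sigma^2)): multiplicative noise with mean exactly 1
        return np.exp(z * sigma - 0.5 * np.square(sigma))

    cv = config.tbv_sd / config.tbv_mean
    tbv_base = config.tbv_mean * mean_one_lognormal(rng_tbv.normal(0.0, 1.0, P), cv)  # (P,)
    subj_dev = mean_one_lognormal(rng_subj.normal(0.0, 1.0, (P, R)), config.subject_sd)  # (P, R)

    scan_sigma = np.array([[config.scan_sigma_at(s, r) for r in rois] for s in steps])  # (J, R)
    scan_eps = mean_one_lognormal(rng_scan.normal(0.0, 1.0, (P, K, J, R)), scan_sigma)  # (P, K, J, R)

    run_sigma = np.array([config.run_sigma_at(s) for s in steps])  # (J,)
    if np.any(run_sigma > 0):
        run_eps = mean_one_lognormal(
            rng_run.normal(0.0, 1.0, (P, K, M, J, R)), run_sigma[:, None]
        )
    else:
        run_eps = np.ones((1, 1, 1, 1, 1))

    base_ratio = np.array([config.base_ratio[r] for r in rois])  # (R,)
    step_bias = np.array([[config.step_bias_at(s, r) for r in rois] for s in steps])  # (J, R)
    tbv_bias = np.array([config.tbv_bias_at(s) for s in steps])  # (J,)

    vol = (
        tbv_base[:, None, None, None, None]
        * base_ratio[None, None, None, None, :]
        * subj_dev[:, None, None, None, :]
        * step_bias[None, None, None, :, :]
        * scan_eps[:, :, None, :, :]
        * run_eps
    )  # (P, K, M, J, R)
    vol = np.broadcast_to(vol, (P, K, M, J, R))
    tbv_rec = tbv_base[:, None] * tbv_bias[None, :]  # (P, J)

    idx_p, idx_k, idx_m, idx_j, idx_r = np.indices((P, K, M, J, R)).reshape(5, -1)
    participant_ids = np.array([f"sub-{i + 1:03d}" for i in range(P)])
    table = pd.DataFrame(
        {
            "participant_id": participant_ids[idx_p],
            "scan_index": idx_k + 1,
            "run_index": idx_m + 1,
            "step": np.array(steps, dtype=object)[idx_j],
            "roi": np.array(rois, dtype=object)[idx_r],
            "volume_mm3": vol.reshape(-1),
            "tbv_mm3": tbv_rec[idx_p, idx_j],
        }
    )
    return table


def generate_label_image(
    grid_shape,
    voxel_dims,
    center,
    radii,
    label: int = 1,
) -> LabelImage:
    """Ellipsoid phantom: voxel v labelled iff sum(((v - center)/radii)^2) <= 1.

    A stand-in for a warped ROI mask in participant space. The ellipsoid
    must fit inside the grid (``center ± radii`` within bounds), otherwise a
    ValueError is raised.
    """
    shape = tuple(int(s) for s in grid_shape)
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(shape) != 3 or center.shape != (3,) or radii.shape != (3,):
        raise ValueError("grid_shape, center and radii must be 3-vectors")
    if np.any(radii <= 0):
        raise ValueError(f"radii must be strictly positive, got {radii}")
    if int(label) <= 0:
        raise ValueError("label must be a positive integer")
    if np.any(center - radii < 0) or np.any(center + radii > np.array(shape) - 1):
        raise ValueError(
            f"ellipsoid (center {center}, radii {radii}) exceeds grid bounds {shape}"
        )
    grids = np.indices(shape, dtype=float)
    dist2 = sum(((grids[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    data = np.where(dist2 <= 1.0, int(label), 0).astype(np.int32)
    return LabelImage(data, np.asarray(voxel_dims, dtype=float))


def perturb_label_image(img: LabelImage, shift, seed: int | None = None) -> LabelImage:
    """Translate the labelled region by an integer voxel shift.

    Integer shifts keep voxel counts exact, so overlap statistics against
    the original have closed-form values. A zero shift returns an identical
    image; a shift that pushes any labelled voxel outside the grid raises.
    ``seed`` is part of the perturbation interface but the current
    perturbation is deterministic and does not consume it.
    """
    shift = np.asarray(shift)
    if shift.shape != (3,) or not np.issubdtype(shift.dtype, np.integer):
        shift_f = np.asarray(shift, dtype=float)
        if shift_f.shape != (3,) or np.any(shift_f != np.rint(shift_f)):
            raise ValueError(f"shift must be a 3-vector of integers, got {shift}")
        shift = np.rint(shift_f).astype(int)
    coords = np.argwhere(img.data != 0)
    new_data = np.zeros_like(img.data)
    if coords.size:
        moved = coords + shift[None, :]
        if np.any(moved < 0) or np.any(moved >= np.array(img.data.shape)[None, :]):
            raise ValueError(f"shift {tuple(shift)} moves the labelled region out of bounds")
        new_data[tuple(moved.T)] = img.data[tuple(coords.T)]
    return LabelImage(new_data, img.voxel_dims.copy(), np.asarray(img.affine).copy())
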