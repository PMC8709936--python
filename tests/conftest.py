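"""Shared fixtures: phantom acquisitions run once per session.

The heavier fixtures execute the full simulate -> register -> fuse
pipeline at the protocol's standard settings and are shared across test
modules; individual tests only measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from gazefuse import (
    AcquisitionParams,
    FusedImage,
    GazeSet,
    GroundTruth,
    RegisteredStack,
    RegistrationResult,
    assemble_stack,
    make_phantom,
    max_pairwise_sd,
    photometric_normalize,
    register,
    simulate_gaze_set,
)
from gazefuse.synthetic import RetinaPhantom


@dataclass
class PipelineRun:
    phantom: RetinaPhantom
    gaze_set: GazeSet
    truth: GroundTruth
    result: RegistrationResult
    stack: RegisteredStack
    fused: FusedImage

    def background_mask(self, pad_px: float = 12.0) -> np.ndarray:
        """Defined canvas pixels at least ``pad_px`` outside every lesion."""
        defined = self.fused.defined_mask()
        h, w = defined.shape
        yy, xx = np.mgrid[0:h, 0:w]
        mask = defined.copy()
        for _, center, radius, _ in self.truth.lesion_geometry(self.stack):
            mask &= np.hypot(xx - center[0], yy - center[1]) >= radius + pad_px
        return mask


def run_pipeline(phantom: RetinaPhantom, params: AcquisitionParams, protocol=None):
    kwargs = {} if protocol is None else {"protocol": protocol}
    gaze_set, truth = simulate_gaze_set(phantom, params=params, **kwargs)
    result = register(gaze_set)
    stack = photometric_normalize(assemble_stack(gaze_set, result))
    fused = max_pairwise_sd(stack)
    return PipelineRun(phantom, gaze_set, truth, result, stack, fused)


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    """Default phantom, default acquisition: the standard study conditions."""
    phantom = make_phantom(seed=1)
    return run_pipeline(phantom, AcquisitionParams(seed=11))


@pytest.fixture(scope="session")
def paired_lesion_run() -> PipelineRun:
    """One druse and one SDD of equal size at mirrored eccentric positions.

    Diagonal mirroring keeps the two 100 µm lesions (65 px radius each)
    well clear of each other so their rim measurements cannot mix.
    """
    phantom = make_phantom(
        lesion_specs=[("druse", (0.8, -0.6), 100.0), ("sdd", (-0.8, 0.6), 100.0)],
        seed=5,
    )
    return run_pipeline(phantom, AcquisitionParams(seed=6))


@pytest.fixture(scope="session")
def small_shift_run() -> PipelineRun:
    """Nine views with true shifts within +/-60 px and rotations within +/-2 deg."""
    phantom = make_phantom(seed=3)
    protocol = [(x, y) for y in (-0.75, 0.0, 0.75) for x in (-0.75, 0.0, 0.75)]
    params = AcquisitionParams(seed=31, rotation_range_deg=2.0)
    return run_pipeline(phantom, params, protocol=protocol)


@pytest.fixture(scope="session")
def young_control_run() -> PipelineRun:
    """Lesion-free phantom, all acquisition variability off."""
    phantom = make_phantom(n_drusen=0, n_sdd=0, n_atrophy=0, seed=2)
    return run_pipeline(phantom, AcquisitionParams.noiseless(seed=3))


def transform_errors(run: PipelineRun) -> tuple[np.ndarray, np.ndarray]:
    """Per-image translation (px) and rotation (deg) recovery errors."""
    anchor_true = run.truth.transforms[run.result.anchor]
    et, er = [], []
    for k, est in enumerate(run.result.transforms):
        true_rel = run.truth.transforms[k].relative_to(anchor_true)
        et.append(np.hypot(est.dx_px - true_rel.dx_px, est.dy_px - true_rel.dy_px))
        er.append(abs(est.theta_deg - true_rel.theta_deg))
    return np.array(et), np.array(er)


def lesion_fused_stats(run: PipelineRun, kind: str) -> list[dict]:
    """Fused-value summaries per lesion of one kind.

    ``margin_mean``/``margin_q75`` summarize the rim band (where the
    gaze modulation lives; the cosine anisotropy leaves roughly half of
    each rim unmodulated, so the upper quartile tracks the bright arc);
    ``region_median`` summarizes the whole lesion footprint.  Lesions
    whose footprint falls outside the defined canvas yield NaN.
    """
    from gazefuse import margin_ring_mask

    values = run.fused.values
    h, w = values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = []
    for lesion, center, radius, width in run.truth.lesion_geometry(run.stack):
        if lesion.kind != kind:
            continue
        defined = np.isfinite(values)
        ring = margin_ring_mask(values.shape, center, radius, width) & defined
        region = (np.hypot(xx - center[0], yy - center[1]) < radius + width) & defined
        out.append({
            "margin_mean": float(values[ring].mean()) if ring.any() else np.nan,
            "margin_q75": float(np.percentile(values[ring], 75))
            if ring.any() else np.nan,
            "region_median": float(np.median(values[region]))
            if region.any() else np.nan,
        })
    return out


def margin_means(run: PipelineRun, kind: str) -> list[float]:
    """Mean fused value over each lesion's margin ring, for one lesion kind."""
    return [s["margin_mean"] for s in lesion_fused_stats(run, kind)]
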