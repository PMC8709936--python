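"""Rigid registration of gaze-shifted retinal images.

The pipeline mirrors classic frequency-domain mosaicking:

1. each image is low-pass filtered (circular mean kernel, default radius
   25 px) to suppress the cone mosaic and shot noise that would otherwise
   dominate the correlation;
2. for every pair of images with sufficient nominal overlap, rotation is
   estimated by phase correlation of log-polar resampled spectral
   magnitudes (the Fourier-Mellin construction; the scale channel is
   computed by the same resampling but forced to 1, as fixational eye
   movements do not rescale the retina), then translation by FFT
   phase correlation after derotation, disambiguated toward the nominal
   gaze offset;
3. a global, quality-weighted linear least-squares solve over the pair
   graph yields one transform per image with the anchor fixed to the
   identity — the all-pairs generalization of averaging each image's
   pairwise offsets.

Conventions: a :class:`PairwiseEstimate` for pair (i, j) stores the
transform mapping image j's pixel coordinates onto image i's;
:class:`RegistrationResult` stores, per image, the transform into the
anchor image's frame.  ``phase_correlate`` itself returns the *content
displacement* of the moving image relative to the reference (the shift
you would apply to the reference content to obtain the moving image),
which is the negative of the mapping translation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import least_squares
from skimage.filters import window as skwindow
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar

from .io import GazeSet
from .fusion import RegisteredStack
from .quantify import overlap_fraction
from .transform import RigidTransform, image_center, warp_rigid


@dataclass(frozen=True)
class PairwiseEstimate:
    """Relative transform estimate for one image pair."""

    i: int
    j: int
    transform: RigidTransform  # maps image j onto image i
    quality: float  # correlation-peak score in [0, 1]

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a pair needs two distinct images")
        if not np.isfinite(self.quality):
            raise ValueError("quality must be finite")


@dataclass
class RegistrationResult:
    """Per-image transforms into the anchor frame, plus provenance."""

    transforms: list[RigidTransform]
    used_pairs: list[PairwiseEstimate]
    anchor: int
    success: bool
    failure_reason: str | None = None
    residual_px: float = 0.0

    def __post_init__(self) -> None:
        if not self.success and not self.failure_reason:
            raise ValueError("failed results must carry a failure_reason")

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "success": self.success,
            "failure_reason": self.failure_reason,
            "residual_px": self.residual_px,
            "transforms": [
                {"dx_px": t.dx_px, "dy_px": t.dy_px, "theta_deg": t.theta_deg}
                for t in self.transforms
            ],
            "pairs": [
                {
                    "i": p.i,
                    "j": p.j,
                    "dx_px": p.transform.dx_px,
                    "dy_px": p.transform.dy_px,
                    "theta_deg": p.transform.theta_deg,
                    "quality": p.quality,
                }
                for p in self.used_pairs
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationResult":
        return cls(
            transforms=[
                RigidTransform(t["dx_px"], t["dy_px"], t["theta_deg"])
                for t in d["transforms"]
            ],
            used_pairs=[
                PairwiseEstimate(
                    p["i"],
                    p["j"],
                    RigidTransform(p["dx_px"], p["dy_px"], p["theta_deg"]),
                    p["quality"],
                )
                for p in d["pairs"]
            ],
            anchor=d["anchor"],
            success=d["success"],
            failure_reason=d.get("failure_reason"),
            residual_px=d.get("residual_px", 0.0),
        )


def lowpass(image: np.ndarray, radius_px: int = 25) -> np.ndarray:
    """Circular mean (pillbox) filter of the given pixel radius.

    Registration-only smoothing; fusion always runs on native images.
    Boundary handling is reflection.  A radius larger than half the
    smaller image dimension is rejected.
    """
    image = np.asarray(image, dtype=float)
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > min(image.shape) // 2:
        raise ValueError(
            f"radius {radius_px} exceeds half the smaller image dimension "
            f"of {image.shape}"
        )
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    kernel = (xx * xx + yy * yy <= radius_px * radius_px).astype(float)
    kernel /= kernel.sum()
    padded = np.pad(image, radius_px, mode="reflect")
    return signal.fftconvolve(padded, kernel, mode="valid")


def _crosspower_peak(a: np.ndarray, b: np.ndarray) -> float:
    """Peak of the normalized cross-power spectrum correlation, in [0, 1]."""
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = np.fft.ifft2(cross / mag).real
    return float(np.clip(corr.max(), 0.0, 1.0))


def _check_correlatable(ref: np.ndarray, mov: np.ndarray) -> None:
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("constant image: spectrum phase is undefined")


def phase_correlate(
    ref: np.ndarray, mov: np.ndarray, upsample: int = 1
) -> tuple[float, float, float]:
    """FFT phase correlation: content shift of ``mov`` relative to ``ref``.

    Returns ``(dx, dy, quality)`` such that ``mov(p) ≈ ref(p - (dx, dy))``,
    refined to 1/upsample px by upsampled cross-correlation around the
    integer peak.  ``quality`` is the normalized cross-power correlation
    peak (1 for a perfect cyclic shift).  Shifts are reported in the
    principal interval (±half the image size); callers with a prior
    should unwrap with :func:`unwrap_shift`.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    _check_correlatable(ref, mov)
    quality = _crosspower_peak(ref, mov)
    shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=int(upsample), normalization="phase"
    )
    # skimage reports the shift that registers mov onto ref; the content
    # displacement is its negative.
    dy, dx = (-shift).tolist()
    return dx, dy, quality


def unwrap_shift(value: float, seed: float, period: float) -> float:
    """Pick the cyclic alias of ``value`` closest to ``seed``."""
    return value - period * round((value - seed) / period)


def _bandlimited_phase_shift(
    a: np.ndarray, b: np.ndarray, max_freq: float = 0.05
) -> tuple[float, float, float]:
    """Phase correlation whitened only below ``max_freq`` cycles/px.

    Content shift of ``b`` relative to ``a`` with parabolic subpixel
    interpolation of the correlation peak, plus a peak-quality score
    normalized so a perfect cyclic shift scores 1.  Restricting the
    whitening to the retained low-frequency band keeps phase
    correlation's unbiasedness without amplifying frequencies the
    low-pass filter suppressed.
    """
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    fy = np.fft.fftfreq(a.shape[0])[:, None]
    fx = np.fft.fftfreq(a.shape[1])[None, :]
    band = (fx * fx + fy * fy) < max_freq * max_freq
    corr = np.fft.ifft2(np.where(band, cross / mag, 0.0)).real
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    quality = float(np.clip(corr[peak] / max(band.mean(), 1e-12), 0.0, 1.0))

    shift = []
    for axis, idx in enumerate(peak):
        n = corr.shape[axis]
        sl = [peak[0], peak[1]]
        vals = []
        for d in (-1, 0, 1):
            sl[axis] = (idx + d) % n
            vals.append(corr[tuple(sl)])
        denom = vals[0] - 2 * vals[1] + vals[2]
        frac = 0.5 * (vals[0] - vals[2]) / denom if denom != 0 else 0.0
        pos = idx + float(np.clip(frac, -0.5, 0.5))
        if pos > n / 2:
            pos -= n
        shift.append(pos)
    # peak location is -(content shift) (see phase_correlate convention)
    return -shift[1], -shift[0], quality


def estimate_rotation(
    ref: np.ndarray,
    mov: np.ndarray,
    upsample: int = 20,
    quality_floor: float = 0.03,
    n_angles: int = 720,
) -> tuple[float, float]:
    """Rotation of ``mov`` relative to ``ref`` via log-polar spectra.

    Both images are Hann-windowed (suppressing spectral edge leakage),
    their centered log-magnitude spectra resampled to log-polar
    coordinates, and the angular shift between the two resampled planes
    recovered by phase correlation — translation-invariant because the
    spectral magnitude discards image translation.  The radial (scale)
    coordinate is part of the same resampling but its shift channel is
    discarded: only translation and rotation are modeled.

    Returns ``(theta_deg, quality)`` with theta in (-45, 45], the
    rotation component of the transform mapping ``mov`` onto ``ref``.
    An ambiguous angular peak (quality below ``quality_floor``, or an
    angle outside the sanity bound) yields theta 0 with the low quality
    reported.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    _check_correlatable(ref, mov)
    win = skwindow("hann", ref.shape)
    radius = min(ref.shape) // 2
    h, w = ref.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - (w - 1) / 2.0, yy - (h - 1) / 2.0)
    # Suppress the rotation-invariant DC blob so it cannot pin the
    # angular correlation to zero.
    dc_mask = 1.0 - np.exp(-(r**2) / (2.0 * 6.0**2))

    def logpolar_spectrum(im: np.ndarray) -> np.ndarray:
        f = np.fft.fftshift(np.abs(np.fft.fft2((im - im.mean()) * win)))
        return warp_polar(
            np.log1p(f) * dc_mask,
            radius=radius,
            scaling="log",
            output_shape=(n_angles, max(ref.shape)),
        )

    p_ref = logpolar_spectrum(ref)
    p_mov = logpolar_spectrum(mov)
    quality = _crosspower_peak(p_ref, p_mov)
    # Plain (unwhitened) correlation for the angular peak: the whitened
    # variant anchors on residual windowing artifacts shared by the two
    # spectra and snaps sub-degree rotations to zero.
    shift, _, _ = phase_cross_correlation(
        p_ref, p_mov, upsample_factor=int(upsample), normalization=None
    )
    # Angular row shift of the moving spectrum; scale channel shift[1] is
    # deliberately ignored (scale forced to 1).
    theta = float(shift[0]) * 360.0 / n_angles
    # The magnitude spectrum has 180 deg symmetry: wrap to (-90, 90].
    theta = theta - 180.0 * np.ceil((theta - 90.0) / 180.0)
    if quality < quality_floor or not (-45.0 < theta <= 45.0):
        return 0.0, min(quality, quality_floor)
    return theta, quality


def _estimate_pair(
    fi: np.ndarray,
    fj: np.ndarray,
    nominal_content_shift: np.ndarray,
    upsample: int,
    estimate_rotations: bool,
    residual: str = "whitened",
) -> tuple[RigidTransform, float]:
    """Relative transform of image j onto image i from filtered images.

    The nominal gaze offset seeds the estimate: both images are cropped
    to the nominally overlapping region (so the phase correlation only
    has to find the small residual due to fixation error, instead of a
    shift comparable to the image size), rotation is estimated on the
    crops via the log-polar spectra, the moving crop derotated, and the
    residual translation found on Hann-windowed crops — windowing
    suppresses the shared frame-edge artifacts that otherwise pin the
    whitened correlation to zero shift.
    """
    h, w = fi.shape
    s0 = np.round(nominal_content_shift).astype(int)  # j(p) ≈ i(p - s0)
    # Region of image i also visible in image j, and its twin in j.
    ox_i, oy_i = max(0, -s0[0]), max(0, -s0[1])
    cw, ch = w - abs(s0[0]), h - abs(s0[1])
    o_i = np.array([ox_i, oy_i])
    o_j = o_i + s0
    ref = fi[o_i[1] : o_i[1] + ch, o_i[0] : o_i[0] + cw]
    mov = fj[o_j[1] : o_j[1] + ch, o_j[0] : o_j[0] + cw]

    if estimate_rotations:
        theta, _ = estimate_rotation(ref, mov, upsample=upsample)
    else:
        theta = 0.0
    if theta != 0.0:
        mov_use, _ = warp_rigid(mov, RigidTransform(0.0, 0.0, theta))
        mov_use = np.where(np.isfinite(mov_use), mov_use, mov.mean())
    else:
        mov_use = mov
    win = skwindow("hann", ref.shape)
    ref_w = (ref - ref.mean()) * win
    mov_w = (mov_use - mov_use.mean()) * win
    if residual == "bandlimited":
        # Whitening restricted to the retained low-frequency band: full
        # whitening can resurrect the strongly attenuated quasi-periodic
        # cone mosaic and lock onto a lattice-aliased peak on very clean
        # images, but resolves the peak position less sharply.
        dx, dy, quality = _bandlimited_phase_shift(ref_w, mov_w)
    else:
        dx, dy, quality = phase_correlate(ref_w, mov_w, upsample=upsample)
    s_res = np.array([dx, dy])

    # Recompose the full-image mapping translation: with crop offsets
    # o_i/o_j, crop pivot cc and image pivot c,
    #   t = -s_res + o_i + cc - c - R(theta) (cc + o_j - c).
    c = image_center((h, w))
    cc = image_center(ref.shape)
    rot = RigidTransform(0.0, 0.0, theta)
    t = -s_res + o_i + cc - c - rot.rotation_matrix() @ (cc + o_j - c)
    return RigidTransform(t[0], t[1], theta), quality


def _bandpass(image: np.ndarray, low_sigma: float = 1.5, high_sigma: float = 8.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass used for subpixel pair refinement."""
    return ndimage.gaussian_filter(image, low_sigma) - ndimage.gaussian_filter(
        image, high_sigma
    )


# Coarse-to-fine bands for intensity refinement: the coarse band excludes
# the quasi-periodic cone mosaic, giving a wide convergence basin; the
# fine band includes it for the final subpixel lock.
_REFINE_BANDS = ((3.0, 12.0), (1.5, 8.0))


def _refine_pair_intensity(
    ref_band: np.ndarray,
    mov_band: np.ndarray,
    seed_tf: RigidTransform,
    margin: int = 8,
    stride: int = 2,
) -> RigidTransform:
    """Jointly polish (dx, dy, theta) by robust intensity least squares.

    Minimizes the band-passed intensity residual between the reference
    and the warped moving image over a *fixed* pixel set (the region
    valid under the seed transform, eroded by ``margin`` to stay clear
    of borders and filter edge effects — a moving support would make the
    objective discontinuous).  A Cauchy loss downweights pixels where
    the two views genuinely disagree, chiefly lesion rims whose
    brightness is gaze-modulated: those are signal downstream but
    outliers here.  The seed must already be within the correct
    correlation basin (a couple of pixels / well under a degree).
    """
    h, w = ref_band.shape
    c = image_center(ref_band.shape)
    qx, qy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inv0 = seed_tf.inverse()
    r0 = inv0.rotation_matrix()
    px0 = r0[0, 0] * (qx - c[0]) + r0[0, 1] * (qy - c[1]) + c[0] + inv0.dx_px
    py0 = r0[1, 0] * (qx - c[0]) + r0[1, 1] * (qy - c[1]) + c[1] + inv0.dy_px
    valid = (
        (px0 >= margin)
        & (px0 <= w - 1 - margin)
        & (py0 >= margin)
        & (py0 <= h - 1 - margin)
    )
    valid[:margin, :] = False
    valid[-margin:, :] = False
    valid[:, :margin] = False
    valid[:, -margin:] = False
    if stride > 1:
        valid &= (np.arange(h)[:, None] % stride == 0) & (
            np.arange(w)[None, :] % stride == 0
        )
    if valid.sum() < 200:
        return seed_tf
    qxv, qyv, refv = qx[valid], qy[valid], ref_band[valid]
    scale = max(float(np.std(refv)), 1e-12)

    def residuals(p: np.ndarray) -> np.ndarray:
        inv = RigidTransform(p[0], p[1], p[2]).inverse()
        rm = inv.rotation_matrix()
        px = rm[0, 0] * (qxv - c[0]) + rm[0, 1] * (qyv - c[1]) + c[0] + inv.dx_px
        py = rm[1, 0] * (qxv - c[0]) + rm[1, 1] * (qyv - c[1]) + c[1] + inv.dy_px
        warped = ndimage.map_coordinates(mov_band, [py, px], order=1, mode="nearest")
        return (refv - warped) / scale

    fit = least_squares(
        residuals,
        [seed_tf.dx_px, seed_tf.dy_px, seed_tf.theta_deg],
        diff_step=[0.05, 0.05, 0.02],
        method="trf",
        loss="cauchy",
        f_scale=0.4,
        max_nfev=40,
        x_scale=[1.0, 1.0, 0.3],
    )
    if not np.all(np.isfinite(fit.x)) or abs(fit.x[2]) >= 45.0:
        return seed_tf
    return RigidTransform(fit.x[0], fit.x[1], fit.x[2])


def _alignment_score(
    fi: np.ndarray, fj: np.ndarray, tf: RigidTransform, min_pixels: int = 500
) -> float:
    """Masked correlation of image i with image j warped by ``tf``, in [0, 1].

    Pearson correlation over the mutually valid region; negative
    correlations clip to 0.  Used to arbitrate between candidate pair
    estimates and as the pair quality consumed by the global solve.
    """
    warped, mask = warp_rigid(fj, tf)
    if mask.sum() < min_pixels:
        return 0.0
    a = fi[mask]
    b = warped[mask]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    ncc = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return float(np.clip(ncc, 0.0, 1.0))


def register_pairs(
    gaze_set: GazeSet,
    radius_px: int = 25,
    min_overlap_frac: float = 0.2,
    upsample: int = 20,
    estimate_rotations: bool = True,
    refine: bool = True,
) -> list[PairwiseEstimate]:
    """Estimate relative transforms for all sufficiently overlapping pairs.

    Every unordered image pair whose nominal overlap (from the manifest
    gaze offsets and field width) is at least ``min_overlap_frac`` is
    registered on low-pass filtered copies.  Two candidate estimates are
    formed — one seeded by the nominal gaze offset (crop to the nominal
    overlap, rotation, then residual translation; see
    :func:`_estimate_pair`) and one blind full-frame phase correlation,
    so the data can override a wrong manifest prior — and the candidate
    whose warped overlap correlates better wins.  The winner is then
    polished by robust intensity least squares on band-passed native
    images (:func:`_refine_pair_intensity`), which resolves the near
    degeneracy between rotation and translation left by small off-center
    overlap regions.  No pair is dropped here — low-quality estimates
    are kept and flagged by their score for :func:`solve_global` to
    weigh or discard.
    """
    images = [im.pixels for im in gaze_set.images]
    gaze = [np.asarray(im.gaze_deg, dtype=float) for im in gaze_set.images]
    ppd = gaze_set.px_per_deg
    filtered = [lowpass(im, radius_px) for im in images]
    banded = (
        [tuple(_bandpass(im, lo, hi) for lo, hi in _REFINE_BANDS) for im in images]
        if refine
        else None
    )

    pairs: list[PairwiseEstimate] = []
    for i in range(len(images)):
        for j in range(i + 1, len(images)):
            dg = gaze[j] - gaze[i]
            if overlap_fraction(gaze_set.fov_deg, dg[0], dg[1]) < min_overlap_frac:
                continue
            fi, fj = filtered[i], filtered[j]
            # Gaze moving by +dg slides the imaged region so the content
            # moves by -dg * px_per_deg.
            candidates = [
                _estimate_pair(
                    fi,
                    fj,
                    nominal_content_shift=-dg * ppd,
                    upsample=upsample,
                    estimate_rotations=estimate_rotations,
                )[0]
            ]
            dx, dy, _ = phase_correlate(fi, fj, upsample=upsample)
            candidates.append(RigidTransform(-dx, -dy, 0.0))
            ranked = sorted(
                candidates, key=lambda tf: _alignment_score(fi, fj, tf), reverse=True
            )
            best, best_score = ranked[0], _alignment_score(fi, fj, ranked[0])
            if refine:
                # Polish the best seed; fall back to the runner-up only
                # when the polished fit still correlates poorly.
                for seed_tf in ranked[:2]:
                    cand = seed_tf
                    for band in range(len(_REFINE_BANDS)):
                        cand = _refine_pair_intensity(
                            banded[i][band], banded[j][band], cand
                        )
                    score = _alignment_score(fi, fj, cand)
                    if score > best_score:
                        best, best_score = cand, score
                    if best_score >= 0.9:
                        break
            pairs.append(
                PairwiseEstimate(i=i, j=j, transform=best, quality=best_score)
            )
    return pairs


def _connected_to_anchor(n: int, pairs: list[PairwiseEstimate], anchor: int) -> set:
    adj: dict[int, set] = {k: set() for k in range(n)}
    for p in pairs:
        adj[p.i].add(p.j)
        adj[p.j].add(p.i)
    seen = {anchor}
    frontier = [anchor]
    while frontier:
        k = frontier.pop()
        for m in adj[k] - seen:
            seen.add(m)
            frontier.append(m)
    return seen


def _solve_relative(
    kept: list[PairwiseEstimate], n_images: int, anchor: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Algebraic consensus: quality-weighted LS on the relative constraints.

    Rotations from ``theta_j - theta_i = r_ij``, then translations from
    ``t_j - t_i = R(theta_i) t_ij``, anchor pinned to identity.  Exact
    for consistent input; with only anchor-pairs present it reduces to
    plain averaging of each image's pairwise offsets.
    """
    free = [k for k in range(n_images) if k != anchor]
    col = {k: c for c, k in enumerate(free)}
    m = len(kept)
    wts = np.array([p.quality for p in kept])
    sw = np.sqrt(wts)

    a_rot = np.zeros((m, len(free)))
    b_rot = np.zeros(m)
    for r, p in enumerate(kept):
        if p.j != anchor:
            a_rot[r, col[p.j]] = 1.0
        if p.i != anchor:
            a_rot[r, col[p.i]] = -1.0
        b_rot[r] = p.transform.theta_deg
    theta_free, *_ = np.linalg.lstsq(a_rot * sw[:, None], b_rot * sw, rcond=None)
    thetas = np.zeros(n_images)
    for k, c in col.items():
        thetas[k] = theta_free[c]

    a_tr = np.zeros((2 * m, 2 * len(free)))
    b_tr = np.zeros(2 * m)
    for r, p in enumerate(kept):
        rhs = RigidTransform(0.0, 0.0, thetas[p.i]).rotation_matrix() @ (
            p.transform.translation
        )
        for ax in range(2):
            row = 2 * r + ax
            if p.j != anchor:
                a_tr[row, 2 * col[p.j] + ax] = 1.0
            if p.i != anchor:
                a_tr[row, 2 * col[p.i] + ax] = -1.0
            b_tr[row] = rhs[ax]
    sw2 = np.repeat(sw, 2)
    t_free, *_ = np.linalg.lstsq(a_tr * sw2[:, None], b_tr * sw2, rcond=None)
    rms = float(np.sqrt(np.mean((a_tr @ t_free - b_tr) ** 2))) if m else 0.0
    trans = np.zeros((n_images, 2))
    for k, c in col.items():
        trans[k] = t_free[2 * c : 2 * c + 2]
    return trans, thetas, rms


def _pair_correspondences(
    p: PairwiseEstimate, shape: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Point correspondences sampling the data-supported overlap of a pair.

    A pairwise estimate is only trustworthy where the two images share
    content: outside the overlap, a small rotation error trades off
    against translation (they are nearly degenerate for off-center
    overlaps).  Sampling the estimated mapping at the overlap centroid
    and four points spread across the overlap rectangle encodes exactly
    the constraint the data supports, with its natural lever arms.
    """
    h, w = shape
    c = image_center(shape)
    t = p.transform.translation
    x0, x1 = max(0.0, t[0]), min(float(w), w + t[0])
    y0, y1 = max(0.0, t[1]), min(float(h), h + t[1])
    if x1 <= x0 or y1 <= y0:
        return []
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    lx, ly = x1 - x0, y1 - y0
    pts_i = [
        np.array([cx, cy]),
        np.array([cx - 0.35 * lx, cy]),
        np.array([cx + 0.35 * lx, cy]),
        np.array([cx, cy - 0.35 * ly]),
        np.array([cx, cy + 0.35 * ly]),
    ]
    inv = p.transform.inverse()
    return [(q, inv.apply(q, c)) for q in pts_i]


def _solve_correspondence(
    kept: list[PairwiseEstimate],
    n_images: int,
    anchor: int,
    image_shape: tuple[int, int],
    rot_prior_weight: float = 0.1,
    n_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Consensus via overlap point correspondences, iterated linear LS.

    Each retained pair contributes the equations ``T_i(q_i) = T_j(q_j)``
    at its overlap sample points (see :func:`_pair_correspondences`),
    plus a weak ``theta_j - theta_i = r_ij`` prior; the resulting
    nonlinear system (rotations enter through R(theta)) is solved by a
    few Gauss-Newton relinearizations.  Weights are the pair qualities.
    """
    c = image_center(image_shape)
    free = [k for k in range(n_images) if k != anchor]
    col = {k: i for i, k in enumerate(free)}
    corr = [(p, _pair_correspondences(p, image_shape)) for p in kept]
    thetas = np.zeros(n_images)
    trans = np.zeros((n_images, 2))
    deg = np.pi / 180.0
    rms = 0.0
    for _ in range(n_iter):
        rows, rhs, wts = [], [], []
        for p, pts in corr:
            for q_i, q_j in pts:
                for ax in range(2):
                    coef = np.zeros(3 * len(free))
                    b = 0.0
                    for sgn, k, q in ((1, p.i, q_i), (-1, p.j, q_j)):
                        rv = RigidTransform(0, 0, thetas[k]).rotation_matrix() @ (
                            q - c
                        )
                        perp = np.array([-rv[1], rv[0]])
                        b -= sgn * (rv[ax] + trans[k][ax])
                        if k != anchor:
                            coef[3 * col[k] + ax] += sgn
                            coef[3 * col[k] + 2] += sgn * perp[ax] * deg
                    rows.append(coef)
                    rhs.append(b)
                    wts.append(p.quality)
            coef = np.zeros(3 * len(free))
            if p.j != anchor:
                coef[3 * col[p.j] + 2] += 1.0
            if p.i != anchor:
                coef[3 * col[p.i] + 2] -= 1.0
            rows.append(coef)
            rhs.append(p.transform.theta_deg - (thetas[p.j] - thetas[p.i]))
            wts.append(rot_prior_weight * p.quality)
        a = np.asarray(rows)
        b = np.asarray(rhs)
        sw = np.sqrt(np.asarray(wts))
        delta, *_ = np.linalg.lstsq(a * sw[:, None], b * sw, rcond=None)
        for k in free:
            i3 = 3 * col[k]
            trans[k] += delta[i3 : i3 + 2]
            thetas[k] += delta[i3 + 2]
        rms = float(np.sqrt(np.mean(((a @ delta - b) * sw) ** 2)))
    return trans, thetas, rms


def solve_global(
    pairs: list[PairwiseEstimate],
    n_images: int,
    anchor: int = 0,
    q_min: float = 0.1,
    image_shape: tuple[int, int] | None = None,
) -> RegistrationResult:
    """Consensus transforms from pairwise estimates by weighted least squares.

    Pairs with quality below ``q_min`` are discarded; the survivors form
    a graph whose every image must connect to the anchor, else the run
    fails (the real-world failure mode: inaccurate fixation or poor
    image quality starves the pair graph).  When ``image_shape`` is
    known the constraints are expressed as point correspondences inside
    each pair's overlap region (:func:`_solve_correspondence`), which
    keeps ill-conditioned corner-overlap pairs from leaking correlated
    rotation/translation errors into the mosaic; without a shape the
    plain relative-offset consensus (:func:`_solve_relative`) is used.
    Either way the anchor is pinned to the identity and, with only
    anchor-pairs present, the solution reduces to averaging each
    image's pairwise offsets.
    """
    kept = [p for p in pairs if p.quality >= q_min]
    connected = _connected_to_anchor(n_images, kept, anchor)
    if len(connected) < n_images:
        missing = sorted(set(range(n_images)) - connected)
        return RegistrationResult(
            transforms=[RigidTransform.identity() for _ in range(n_images)],
            used_pairs=kept,
            anchor=anchor,
            success=False,
            failure_reason=(
                "insufficient overlap/quality: images "
                f"{missing} are disconnected from the anchor"
            ),
        )
    if image_shape is not None:
        trans, thetas, rms = _solve_correspondence(
            kept, n_images, anchor, image_shape
        )
    else:
        trans, thetas, rms = _solve_relative(kept, n_images, anchor)
    transforms = [
        RigidTransform.identity()
        if k == anchor
        else RigidTransform(trans[k][0], trans[k][1], thetas[k])
        for k in range(n_images)
    ]
    return RegistrationResult(
        transforms=transforms,
        used_pairs=kept,
        anchor=anchor,
        success=True,
        residual_px=rms,
    )


def assemble_stack(gaze_set: GazeSet, result: RegistrationResult) -> RegisteredStack:
    """Place the native (unfiltered) images onto a common NaN-padded canvas.

    The canvas is the union bounding box of all transformed image
    footprints in the anchor image's frame (the anchor — by protocol the
    central, straight-ahead image — stays where it is and the bounds
    expand around it).  Each image is resampled bilinearly; canvas
    pixels a given image never covered are NaN in that layer and false
    in its mask, so fusion statistics skip them.
    """
    if not result.success:
        raise ValueError(f"registration failed: {result.failure_reason}")
    h, w = gaze_set.shape
    c = image_center((h, w))
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]]
    )
    mapped = np.vstack([t.apply(corners, c) for t in result.transforms])
    lo = mapped.min(axis=0)
    hi = mapped.max(axis=0)
    # Snap near-integer bounds so subpixel estimation noise cannot pad
    # the canvas by a spurious pixel on protocol-exact shifts.
    snap = np.abs(lo - np.round(lo)) < 0.01
    lo[snap] = np.round(lo[snap])
    snap = np.abs(hi - np.round(hi)) < 0.01
    hi[snap] = np.round(hi[snap])
    x0, y0 = np.floor(lo).astype(int)
    x1, y1 = np.ceil(hi).astype(int)
    out_shape = (y1 - y0 + 1, x1 - x0 + 1)

    layers = np.empty((len(gaze_set.images), *out_shape))
    masks = np.empty((len(gaze_set.images), *out_shape), dtype=bool)
    for k, (im, t) in enumerate(zip(gaze_set.images, result.transforms)):
        layers[k], masks[k] = warp_rigid(
            im.pixels, t, out_shape=out_shape, out_origin=(x0, y0)
        )
    return RegisteredStack(
        layers=layers,
        masks=masks,
        canvas_origin=(float(x0), float(y0)),
        anchor=result.anchor,
    )


def register(
    gaze_set: GazeSet,
    radius_px: int = 25,
    min_overlap_frac: float = 0.2,
    q_min: float = 0.1,
    anchor: int | None = None,
    upsample: int = 20,
) -> RegistrationResult:
    """Convenience wrapper: pairwise estimation plus the global solve.

    The anchor defaults to the image whose gaze offset is closest to
    (0, 0), matching the acquisition protocol's straight-ahead image.
    """
    if anchor is None:
        norms = [np.hypot(*im.gaze_deg) for im in gaze_set.images]
        anchor = int(np.argmin(norms))
    pairs = register_pairs(
        gaze_set,
        radius_px=radius_px,
        min_overlap_frac=min_overlap_frac,
        upsample=upsample,
    )
    return solve_global(
        pairs,
        len(gaze_set.images),
        anchor=anchor,
        q_min=q_min,
        image_shape=gaze_set.shape,
    )
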