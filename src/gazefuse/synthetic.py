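"""Synthetic retinal phantoms with gaze-dependent lesion contrast.

The generator emulates the gaze-shifted acquisition protocol: a master
en-face "retina" (jittered hexagonal cone mosaic over a smooth fundus
background) carries three lesion types with the optical signatures seen
in flood-illumination adaptive-optics imaging of age-related macular
degeneration:

- **drusen** — annuli with a darker center and a bright rim whose
  brightness is anisotropic: the rim half facing away from the window
  center (toward the field edge) brightens with lesion eccentricity;
- **SDDs** (subretinal drusenoid deposits) — the same annular geometry
  with *inverted* polarity (near-edge rim darkens) and lower modulation
  amplitude;
- **atrophy** — static hyper-bright patches with no gaze modulation.

The rim modulation is a minimal phenomenological model: rim intensity at
angular position phi around the lesion is scaled by

    1 + polarity * amplitude * e * cos(phi - psi)

where psi points from the window center toward the lesion and e is the
lesion's eccentricity fraction within the window (0 at center, 1 at the
field edge).  Only the sign and monotonicity of this modulation are
meaningful; the true functional form in vivo is unknown.

Every render returns the exact rigid transform that was applied, so
registration and fusion can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import GazeImage, GazeSet
from .transform import RigidTransform, image_center

LESION_KINDS = ("druse", "sdd", "atrophy")
DEFAULT_PROTOCOL = tuple(
    (float(x), float(y)) for y in (-2.0, 0.0, 2.0) for x in (-2.0, 0.0, 2.0)
)
DEFAULT_BEAMS = ((0.0, 0.0), (0.0, -2.0), (2.0, 0.0), (0.0, 2.0), (-2.0, 0.0))

# Master-image photometry (arbitrary intensity units on a ~100 baseline).
BASE_LEVEL = 100.0
CONE_AMPLITUDE = 15.0
CONE_SPACING_PX = 6.0
FIELD_AMPLITUDE = 8.0
DRUSE_RIM_GAIN = 35.0
DRUSE_DIP_DEPTH = 20.0
SDD_RIM_GAIN = 20.0
ATROPHY_GAIN = 45.0


@dataclass
class Lesion:
    """One simulated deposit with its gaze-contrast behaviour."""

    kind: str
    center_deg: tuple[float, float]
    diameter_um: float
    modulation_amplitude: float
    polarity: int
    inner_diameter_um: float = 0.0
    confluent: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"kind must be one of {LESION_KINDS}")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        expected = {"druse": 1, "sdd": -1, "atrophy": 0}[self.kind]
        if self.polarity != expected:
            raise ValueError(f"{self.kind} must have polarity {expected}")
        if self.kind == "atrophy" and self.modulation_amplitude != 0:
            raise ValueError("atrophy is gaze-invariant: amplitude must be 0")


@dataclass
class _RimStamp:
    """Precomputed rim rendering of one lesion on the master grid."""

    lesion_index: int
    sy: slice
    sx: slice
    rim: np.ndarray
    phi: np.ndarray  # angle of each stamp pixel around the lesion center


@dataclass
class RetinaPhantom:
    """Master retina image plus lesion truth and rendering metadata."""

    master: np.ndarray  # static content: background + dips + atrophy
    lesions: list[Lesion]
    px_per_deg: float
    scale_um_per_px: float = 0.77
    rim_stamps: list[_RimStamp] = field(default_factory=list)

    @property
    def center_px(self) -> np.ndarray:
        h, w = self.master.shape
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    def lesion_center_px(self, lesion: Lesion) -> np.ndarray:
        return self.center_px + np.asarray(lesion.center_deg) * self.px_per_deg

    def lesion_radius_px(self, lesion: Lesion) -> float:
        return lesion.diameter_um / self.scale_um_per_px / 2.0


@dataclass
class AcquisitionParams:
    """Per-acquisition variability of the simulated device and eye."""

    fixation_sigma_deg: float = 0.1
    rotation_range_deg: float = 1.0
    gain_jitter: float = 0.03
    offset_jitter: float = 2.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fixation_sigma_deg",
            "rotation_range_deg",
            "gain_jitter",
            "offset_jitter",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "AcquisitionParams":
        """All variability off: renders reproduce nominal geometry exactly."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, seed)


@dataclass
class GroundTruth:
    """What the simulator actually did: transforms and lesion table."""

    transforms: list[RigidTransform]
    lesions: list[Lesion]
    anchor_index: int
    px_per_deg: float
    scale_um_per_px: float
    window_shape: tuple[int, int]

    def lesion_centers_anchor_px(self) -> np.ndarray:
        """Lesion centers (xy, px) in the nominal straight-ahead frame."""
        if not self.lesions:
            return np.empty((0, 2))
        return np.array(
            [np.asarray(l.center_deg) * self.px_per_deg for l in self.lesions]
        ) + image_center(self.window_shape)

    def lesion_centers_canvas(self, stack) -> np.ndarray:
        """Lesion centers as canvas xy of a stack anchored on ``anchor_index``.

        The registration canvas lives in the *acquired* anchor image's
        pixel frame, which differs from the nominal straight-ahead frame
        by that image's own fixation error and rotation.
        """
        pts = self.lesion_centers_anchor_px()
        if pts.size == 0:
            return pts
        c = image_center(self.window_shape)
        in_anchor_img = self.transforms[self.anchor_index].inverse().apply(pts, c)
        return in_anchor_img - np.asarray(stack.canvas_origin)

    def lesion_geometry(self, stack) -> list[tuple[Lesion, np.ndarray, float, float]]:
        """Per lesion: (lesion, canvas center xy, outer radius px, rim width px)."""
        centers = self.lesion_centers_canvas(stack)
        out = []
        for lesion, center in zip(self.lesions, centers):
            r = lesion.diameter_um / self.scale_um_per_px / 2.0
            out.append((lesion, center, r, _rim_width_px(r)))
        return out

    def lesion_table(self) -> pd.DataFrame:
        """Lesion truth with centers both in degrees and in anchor-frame px."""
        centers_px = self.lesion_centers_anchor_px()
        return pd.DataFrame(
            [
                {
                    "kind": l.kind,
                    "cx_deg": l.center_deg[0],
                    "cy_deg": l.center_deg[1],
                    "cx_px": centers_px[k][0],
                    "cy_px": centers_px[k][1],
                    "diameter_um": l.diameter_um,
                    "inner_diameter_um": l.inner_diameter_um,
                    "modulation_amplitude": l.modulation_amplitude,
                    "polarity": l.polarity,
                    "confluent": l.confluent,
                }
                for k, l in enumerate(self.lesions)
            ],
            columns=[
                "kind",
                "cx_deg",
                "cy_deg",
                "cx_px",
                "cy_px",
                "diameter_um",
                "inner_diameter_um",
                "modulation_amplitude",
                "polarity",
                "confluent",
            ],
        )

    def save(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tpath = out_dir / "true_transforms.json"
        tpath.write_text(
            json.dumps(
                {
                    "anchor_index": self.anchor_index,
                    "px_per_deg": self.px_per_deg,
                    "transforms": [
                        {"dx_px": t.dx_px, "dy_px": t.dy_px, "theta_deg": t.theta_deg}
                        for t in self.transforms
                    ],
                },
                indent=2,
            )
        )
        lpath = out_dir / "lesions.csv"
        self.lesion_table().to_csv(lpath, index=False)
        return tpath, lpath


def _rim_width_px(radius_px: float) -> float:
    return float(np.clip(0.2 * radius_px, 1.5, 10.0))


def _smooth_disc(rho: np.ndarray, radius: float, edge: float = 2.0) -> np.ndarray:
    return np.clip((radius - rho) / edge + 0.5, 0.0, 1.0)


def make_phantom(
    n_drusen: int = 10,
    n_sdd: int = 2,
    n_atrophy: int = 2,
    diameter_range_um: tuple[float, float] = (11.0, 320.0),
    px_per_deg: float = 75.0,
    seed: int = 0,
    fov_deg: float = 4.0,
    gaze_extent_deg: float = 2.0,
    scale_um_per_px: float = 0.77,
    druse_amplitude: float = 0.5,
    sdd_amplitude: float = 0.25,
    lesion_specs: list[tuple[str, tuple[float, float], float]] | None = None,
) -> RetinaPhantom:
    """Build a master retina with lesions and precomputed rim stamps.

    The master covers the full protocol footprint (field width plus the
    gaze excursion on each side) with a safety margin for fixation error
    and rotation.  Lesion diameters are drawn log-uniformly from
    ``diameter_range_um`` — drusen populations are dominated by small
    deposits — and converted to pixels through ``scale_um_per_px``.
    Lesions are placed without mutual overlap where possible; when
    bounded retries fail the lesion is placed anyway and flagged
    confluent, as confluent drusen are a real and common presentation.
    Deterministic given ``seed``.

    ``lesion_specs`` — a list of ``(kind, (cx_deg, cy_deg), diameter_um)``
    tuples — bypasses random lesion generation entirely for controlled
    experiments; the counts and diameter range are then ignored.
    """
    if min(n_drusen, n_sdd, n_atrophy) < 0:
        raise ValueError("lesion counts must be non-negative")
    lo, hi = diameter_range_um
    if not 0 < lo <= hi:
        raise ValueError("invalid diameter range")
    rng = np.random.default_rng(seed)
    margin_deg = 0.5
    half_deg = fov_deg / 2.0 + gaze_extent_deg + margin_deg
    side = int(round(2 * half_deg * px_per_deg)) | 1  # odd side, exact center
    center = (side - 1) / 2.0

    # Background: smooth fundus field + jittered hexagonal cone mosaic.
    master = np.full((side, side), BASE_LEVEL)
    coarse = rng.normal(0.0, 1.0, (side // 24 + 2, side // 24 + 2))
    fld = ndimage.zoom(coarse, side / np.array(coarse.shape), order=3)[:side, :side]
    master += FIELD_AMPLITUDE * fld / max(fld.std(), 1e-12)

    sy = CONE_SPACING_PX * np.sqrt(3) / 2
    impulses = np.zeros((side, side))
    rows = np.arange(0, side + sy, sy)
    for r_i, y in enumerate(rows):
        xs = np.arange(0, side + CONE_SPACING_PX, CONE_SPACING_PX)
        xs = xs + (CONE_SPACING_PX / 2 if r_i % 2 else 0.0)
        xs = xs + rng.normal(0, 0.08 * CONE_SPACING_PX, xs.size)
        ys = y + rng.normal(0, 0.08 * CONE_SPACING_PX, xs.size)
        amp = CONE_AMPLITUDE * (1 + 0.2 * rng.standard_normal(xs.size))
        xi = np.round(xs).astype(int)
        yi = np.round(ys).astype(int)
        ok = (xi >= 0) & (xi < side) & (yi >= 0) & (yi < side)
        np.add.at(impulses, (yi[ok], xi[ok]), amp[ok])
    # Spread each impulse into a Gaussian spot; rescale so the spot peak
    # carries the drawn cone amplitude rather than its mass.
    cone_sigma = 1.5
    master += ndimage.gaussian_filter(impulses, cone_sigma) * (
        2 * np.pi * cone_sigma**2
    )

    if lesion_specs is not None:
        requested = [
            (kind, float(d_um), np.asarray(pos, dtype=float) * px_per_deg)
            for kind, pos, d_um in lesion_specs
        ]
    else:
        kinds = ["druse"] * n_drusen + ["sdd"] * n_sdd + ["atrophy"] * n_atrophy
        requested = [
            (kind, float(np.exp(rng.uniform(np.log(lo), np.log(hi)))), None)
            for kind in kinds
        ]
    lesions: list[Lesion] = []
    stamps: list[_RimStamp] = []
    placed: list[tuple[np.ndarray, float]] = []
    place_lim_deg = gaze_extent_deg + 0.5

    for kind, d_um, fixed_pos in requested:
        r_px = d_um / scale_um_per_px / 2.0
        confluent = False
        if fixed_pos is not None:
            pos = fixed_pos
            confluent = any(
                np.linalg.norm(pos - q) <= 0.9 * (r_px + rq) for q, rq in placed
            )
        else:
            lim = min(place_lim_deg * px_per_deg, side / 2.0 - r_px - 3.0)
            lim = max(lim, 1.0)
            for attempt in range(200):
                pos = rng.uniform(-lim, lim, 2)
                if all(
                    np.linalg.norm(pos - q) > 0.9 * (r_px + rq) for q, rq in placed
                ):
                    break
            else:
                confluent = True
        placed.append((pos, r_px))

        amp = {"druse": druse_amplitude, "sdd": sdd_amplitude, "atrophy": 0.0}[kind]
        pol = {"druse": 1, "sdd": -1, "atrophy": 0}[kind]
        w = _rim_width_px(r_px)
        lesion = Lesion(
            kind=kind,
            center_deg=(pos[0] / px_per_deg, pos[1] / px_per_deg),
            diameter_um=d_um,
            modulation_amplitude=amp,
            polarity=pol,
            inner_diameter_um=max(2 * (r_px - w), 0.0) * scale_um_per_px,
            confluent=confluent,
        )
        lesions.append(lesion)

        cx, cy = center + pos
        ext = int(np.ceil(r_px + 3 * w)) + 2
        y0, y1 = max(0, int(cy) - ext), min(side, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(side, int(cx) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rho = np.hypot(xx - cx, yy - cy)
        if kind == "atrophy":
            master[y0:y1, x0:x1] += ATROPHY_GAIN * _smooth_disc(rho, r_px)
            continue
        sigma = w / 2.3548  # FWHM = rim width; outer half-max sits at r_px
        rim_mid = r_px - w / 2.0
        gain = DRUSE_RIM_GAIN if kind == "druse" else SDD_RIM_GAIN
        rim = gain * np.exp(-((rho - rim_mid) ** 2) / (2 * sigma**2))
        if kind == "druse":
            master[y0:y1, x0:x1] -= DRUSE_DIP_DEPTH * _smooth_disc(rho, r_px - w)
        phi = np.arctan2(yy - cy, xx - cx)
        stamps.append(
            _RimStamp(
                lesion_index=len(lesions) - 1,
                sy=slice(y0, y1),
                sx=slice(x0, x1),
                rim=rim,
                phi=phi,
            )
        )

    return RetinaPhantom(
        master=master,
        lesions=lesions,
        px_per_deg=px_per_deg,
        scale_um_per_px=scale_um_per_px,
        rim_stamps=stamps,
    )


def _modulated_master(
    phantom: RetinaPhantom,
    window_center_master: np.ndarray,
    fov_deg: float,
    beam_deg: tuple[float, float] | None,
    beam_amplitude_factor: float,
) -> np.ndarray:
    """Master copy with each rim scaled by its view-dependent modulation."""
    mod = phantom.master.copy()
    for stamp in phantom.rim_stamps:
        lesion = phantom.lesions[stamp.lesion_index]
        if beam_deg is None:
            delta = phantom.lesion_center_px(lesion) - window_center_master
            dist_deg = float(np.hypot(*delta)) / phantom.px_per_deg
            ecc = min(1.0, dist_deg / (fov_deg / 2.0))
            psi = np.arctan2(delta[1], delta[0])
            amp = lesion.modulation_amplitude
        else:
            # Directional mode: the anisotropy axis follows the pupil
            # entry position of the beam, not the lesion's place in the
            # field, and the effect is weaker.
            ecc = min(1.0, float(np.hypot(*beam_deg)) / (fov_deg / 2.0))
            psi = np.arctan2(beam_deg[1], beam_deg[0])
            amp = lesion.modulation_amplitude * beam_amplitude_factor
        factor = 1.0 + lesion.polarity * amp * ecc * np.cos(stamp.phi - psi)
        mod[stamp.sy, stamp.sx] += stamp.rim * factor
    return mod


def render_gaze_image(
    phantom: RetinaPhantom,
    gaze_deg: tuple[float, float],
    fov_deg: float = 4.0,
    params: AcquisitionParams | None = None,
    rng: np.random.Generator | None = None,
    image_id: str = "",
    beam_deg: tuple[float, float] | None = None,
    beam_amplitude_factor: float = 0.4,
) -> tuple[GazeImage, RigidTransform]:
    """Render one acquisition; returns the image and its true transform.

    The window is cropped at the requested gaze offset plus a random
    fixation error, rotated by a small random angle, rim-modulated per
    lesion, then degraded with gain/offset jitter and additive noise.
    The returned :class:`RigidTransform` maps the rendered image's pixel
    coordinates into the nominal straight-ahead frame.
    """
    params = params or AcquisitionParams()
    rng = rng or np.random.default_rng(params.seed)
    gaze = np.asarray(gaze_deg, dtype=float)
    ppd = phantom.px_per_deg
    w = int(round(fov_deg * ppd))
    c = image_center((w, w))

    eps = rng.normal(0.0, params.fixation_sigma_deg, 2)
    theta = (
        rng.uniform(-params.rotation_range_deg, params.rotation_range_deg)
        if params.rotation_range_deg > 0
        else 0.0
    )
    t = (gaze + eps) * ppd
    true_tf = RigidTransform(t[0], t[1], theta)

    wc_master = phantom.center_px + (gaze + eps) * ppd
    mod = _modulated_master(
        phantom, wc_master, fov_deg, beam_deg, beam_amplitude_factor
    )

    # Sample the window: rendered pixel p lives at A(p) on the master,
    # A = (nominal->master offset) ∘ true_tf.
    m0 = phantom.center_px - c
    qx, qy = np.meshgrid(np.arange(w, dtype=float), np.arange(w, dtype=float))
    rmat = true_tf.rotation_matrix()
    mx = rmat[0, 0] * (qx - c[0]) + rmat[0, 1] * (qy - c[1]) + c[0] + t[0] + m0[0]
    my = rmat[1, 0] * (qx - c[0]) + rmat[1, 1] * (qy - c[1]) + c[1] + t[1] + m0[1]
    mh, mw = mod.shape
    if mx.min() < 0 or my.min() < 0 or mx.max() > mw - 1 or my.max() > mh - 1:
        raise ValueError(
            f"gaze {tuple(gaze)} (+ fixation error) pushes the window outside "
            "the phantom master"
        )
    pixels = ndimage.map_coordinates(mod, [my, mx], order=1)

    gain = 1.0 + (rng.normal(0.0, params.gain_jitter) if params.gain_jitter else 0.0)
    offset = rng.normal(0.0, params.offset_jitter) if params.offset_jitter else 0.0
    pixels = pixels * gain + offset
    if params.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, params.noise_sigma, pixels.shape)

    return GazeImage(pixels=pixels, gaze_deg=tuple(gaze), id=image_id), true_tf


def simulate_gaze_set(
    phantom: RetinaPhantom,
    protocol=DEFAULT_PROTOCOL,
    fov_deg: float = 4.0,
    params: AcquisitionParams | None = None,
) -> tuple[GazeSet, GroundTruth]:
    """Render the full acquisition protocol; deterministic given the seed.

    The default protocol is the nine-position grid {-2, 0, 2}² degrees
    (2-degree steps give cardinal neighbors 50% and diagonal neighbors
    25% nominal overlap at a 4-degree field).
    """
    params = params or AcquisitionParams()
    rng = np.random.default_rng(params.seed)
    images, transforms = [], []
    for k, gaze in enumerate(protocol):
        gid = f"gx{gaze[0]:+g}y{gaze[1]:+g}"
        img, tf = render_gaze_image(
            phantom, gaze, fov_deg=fov_deg, params=params, rng=rng, image_id=gid
        )
        images.append(img)
        transforms.append(tf)
    gaze_set = GazeSet(
        images=images,
        fov_deg=fov_deg,
        scale_um_per_px=phantom.scale_um_per_px,
    )
    norms = [np.hypot(*g) for g in protocol]
    truth = GroundTruth(
        transforms=transforms,
        lesions=list(phantom.lesions),
        anchor_index=int(np.argmin(norms)),
        px_per_deg=phantom.px_per_deg,
        scale_um_per_px=phantom.scale_um_per_px,
        window_shape=gaze_set.shape,
    )
    return gaze_set, truth


def simulate_directional_set(
    phantom: RetinaPhantom,
    beams=DEFAULT_BEAMS,
    fov_deg: float = 4.0,
    params: AcquisitionParams | None = None,
    beam_amplitude_factor: float = 0.4,
) -> list[np.ndarray]:
    """Render the directional-imaging protocol: fixed gaze, displaced beam.

    Fixation (hence field of view) stays put while the illumination beam
    moves to the pupil positions in ``beams`` (default: center plus the
    four cardinal displacements).  The images are returned already
    co-registered, as the variant's acquisition produces after its own
    alignment step; photometric jitter and noise still apply.
    """
    params = params or AcquisitionParams()
    rng = np.random.default_rng(params.seed)
    still = AcquisitionParams(
        fixation_sigma_deg=0.0,
        rotation_range_deg=0.0,
        gain_jitter=params.gain_jitter,
        offset_jitter=params.offset_jitter,
        noise_sigma=params.noise_sigma,
        seed=params.seed,
    )
    out = []
    for k, beam in enumerate(beams):
        img, _ = render_gaze_image(
            phantom,
            (0.0, 0.0),
            fov_deg=fov_deg,
            params=still,
            rng=rng,
            image_id=f"beam{k}",
            beam_deg=beam,
            beam_amplitude_factor=beam_amplitude_factor,
        )
        out.append(img.pixels)
    return out
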