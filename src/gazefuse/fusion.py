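"""Per-pixel statistical fusion of a registered gaze-image stack.

A set of co-registered en-face images is combined pixel-by-pixel over the
*defined* layer values only (pixels a layer never covered are NaN and
carry an explicit mask).  Structures whose local brightness changes with
gaze position — drusen margins, subretinal drusenoid deposits — produce
large per-pixel dispersion and light up in SD-type statistics, while
gaze-invariant structures (the cone mosaic on average, atrophic patches)
cancel out.

Statistics use the sample (n-1) convention throughout, which makes the
two-sample SD of a pair equal ``|x_i - x_j| / sqrt(2)`` and gives the
clean dominance property ``max_pairwise_sd >= sd`` with equality at
coverage 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_MIN_COVERAGE = {
    "sum": 1,
    "mean": 1,
    "sd": 2,
    "variance": 2,
    "covariance": 2,
    "max_pair_sd": 2,
}

STATS = tuple(_MIN_COVERAGE)


@dataclass
class RegisteredStack:
    """Co-aligned image layers on a common canvas.

    ``layers`` is ``(n, H, W)`` float with NaN at undefined pixels;
    ``masks`` the matching boolean defined-maps; ``canvas_origin`` the xy
    offset of canvas pixel (0, 0) in the anchor image's frame; ``anchor``
    the index of the anchor layer.
    """

    layers: np.ndarray
    masks: np.ndarray
    canvas_origin: tuple[float, float] = (0.0, 0.0)
    anchor: int = 0

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.layers.ndim != 3 or self.layers.shape[0] < 1:
            raise ValueError("stack needs >= 1 layer of 2-D images")
        if self.masks.shape != self.layers.shape:
            raise ValueError("masks and layers must share dimensions")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    def coverage(self) -> np.ndarray:
        return self.masks.sum(axis=0)


@dataclass
class FusedImage:
    """A per-pixel statistic over the stack plus its coverage map."""

    values: np.ndarray
    coverage: np.ndarray
    stat: str
    inverted: bool = False
    meta: dict = field(default_factory=dict)

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask()]


def _masked(stack: RegisteredStack) -> np.ndarray:
    data = stack.layers.copy()
    data[~stack.masks] = np.nan
    return data


def fuse(stack: RegisteredStack, stat: str = "max_pair_sd") -> FusedImage:
    """Fuse a stack with the named per-pixel statistic.

    Per pixel, over the n defined layer values x_1..x_n:

    - ``sum``, ``mean``: the obvious reductions (n >= 1);
    - ``variance``/``sd``: sample variance / SD, n-1 denominator (n >= 2);
    - ``covariance``: absolute mean over pairs i<j of
      (x_i - mu)(x_j - mu); algebraically equal to variance / n;
    - ``max_pair_sd``: see :func:`max_pairwise_sd`.

    Pixels with coverage below the statistic's minimum are NaN.
    """
    if stat not in _MIN_COVERAGE:
        raise ValueError(f"unknown statistic {stat!r}; choose from {STATS}")
    if stat == "max_pair_sd":
        return max_pairwise_sd(stack)

    data = _masked(stack)
    cov = stack.coverage()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "sum":
            values = np.nansum(data, axis=0)
        elif stat == "mean":
            values = np.nanmean(data, axis=0)
        else:
            var = np.nanvar(data, axis=0, ddof=1)
            if stat == "variance":
                values = var
            elif stat == "sd":
                values = np.sqrt(var)
            else:  # covariance: mean pairwise deviation product = var / n
                values = var / np.maximum(cov, 1)
    values = np.where(cov >= _MIN_COVERAGE[stat], values, np.nan)
    return FusedImage(values=values, coverage=cov, stat=stat)


def max_pairwise_sd(stack: RegisteredStack) -> FusedImage:
    """Maximum two-sample SD over all layer pairs, per pixel.

    The two-sample sample SD of (x_i, x_j) is |x_i - x_j| / sqrt(2), so
    the maximum over pairs reduces to (max - min) / sqrt(2) over the
    defined values; undefined where fewer than two layers contribute.
    """
    data = _masked(stack)
    cov = stack.coverage()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanmax(data, axis=0) - np.nanmin(data, axis=0)
    values = np.where(cov >= 2, spread / np.sqrt(2.0), np.nan)
    return FusedImage(values=values, coverage=cov, stat="max_pair_sd")


def invert(fused: FusedImage) -> FusedImage:
    """Flip contrast on defined pixels: v -> (max - v) + min.

    An involution on the defined region; undefined pixels stay undefined.
    """
    defined = fused.defined_mask()
    if not defined.any():
        raise ValueError("cannot invert an all-undefined image")
    lo = np.nanmin(fused.values)
    hi = np.nanmax(fused.values)
    values = np.where(defined, (hi - fused.values) + lo, np.nan)
    return FusedImage(
        values=values,
        coverage=fused.coverage.copy(),
        stat=fused.stat,
        inverted=not fused.inverted,
        meta=dict(fused.meta),
    )


def photometric_normalize(stack: RegisteredStack) -> RegisteredStack:
    """Match each layer's gain/offset to the anchor layer.

    Per-acquisition brightness and contrast drift (illumination, pupil
    centration) would otherwise masquerade as gaze-dependent signal in
    SD-type fusion.  Each non-anchor layer is linearly rescaled so that
    its mean and SD over the pixels mutually defined with the anchor
    match the anchor's over that same region.  Layers sharing no defined
    pixel with the anchor are left unchanged with a warning.
    """
    layers = stack.layers.copy()
    anchor = stack.anchor
    amask = stack.masks[anchor]
    for k in range(stack.n_layers):
        if k == anchor:
            continue
        mutual = stack.masks[k] & amask
        if not mutual.any():
            warnings.warn(
                f"layer {k} shares no defined pixels with the anchor; "
                "left unnormalized",
                stacklevel=2,
            )
            continue
        a = stack.layers[anchor][mutual]
        b = stack.layers[k][mutual]
        b_sd = b.std()
        gain = a.std() / b_sd if b_sd > 0 else 1.0
        layers[k] = (stack.layers[k] - b.mean()) * gain + a.mean()
        layers[k][~stack.masks[k]] = np.nan
    return RegisteredStack(
        layers=layers,
        masks=stack.masks.copy(),
        canvas_origin=stack.canvas_origin,
        anchor=anchor,
    )


def directional_fuse(aligned_images: list[np.ndarray]) -> FusedImage:
    """SD z-projection of co-registered, same-field images.

    The directional-imaging variant: fixation (hence field of view) is
    fixed while the illumination beam is displaced in the pupil, and the
    aligned stack is collapsed by the per-pixel sample SD.  Identical
    math to ``fuse(stat='sd')`` on a fully defined stack.
    """
    if len(aligned_images) < 2:
        raise ValueError("directional fusion needs >= 2 images")
    shapes = {np.asarray(im).shape for im in aligned_images}
    if len(shapes) != 1:
        raise ValueError(f"images must share dimensions, got {sorted(shapes)}")
    data = np.stack([np.asarray(im, dtype=float) for im in aligned_images])
    stack = RegisteredStack(layers=data, masks=np.isfinite(data))
    out = fuse(stack, "sd")
    out.stat = "sd"
    out.meta["mode"] = "directional"
    return out
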