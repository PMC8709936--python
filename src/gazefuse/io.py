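"""Reading and writing gaze-image sets, ellipse ROI tables, and fused outputs.

A *gaze set* is a directory of grayscale images plus a JSON manifest
listing, per image, its file path and the nominal fixation offset in
degrees at which it was acquired.  All pixel work inside the package is
floating point; intensities are preserved exactly as read (no histogram
equalization, no rescaling) because the fusion statistics downstream are
intensity-sensitive.

Coordinates are 0-based with pixel centers at integer positions, x
rightward and y downward.  Gaze offsets are abstract planar degrees —
no anatomical direction convention is imposed.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

ROI_HEADER = ["id", "modality", "cx", "cy", "a", "b", "angle_deg", "label"]
ROI_MODALITIES = ("color_fundus", "native_fiao", "gaze_dependent")


@dataclass
class GazeImage:
    """One acquisition: pixel array plus its nominal gaze offset."""

    pixels: np.ndarray
    gaze_deg: tuple[float, float]
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"image {self.id!r}: pixels must be 2-D and non-empty")
        self.gaze_deg = (float(self.gaze_deg[0]), float(self.gaze_deg[1]))
        if not np.all(np.isfinite(self.gaze_deg)):
            raise ValueError(f"image {self.id!r}: gaze offset must be finite")


@dataclass
class GazeSet:
    """An ordered set of same-sized gaze images with acquisition metadata."""

    images: list[GazeImage]
    fov_deg: float = 4.0
    scale_um_per_px: float = 0.77

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("a gaze set needs at least 2 images")
        shapes = {im.pixels.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"images differ in dimensions: {sorted(shapes)}")
        offsets = [im.gaze_deg for im in self.images]
        if len(set(offsets)) != len(offsets):
            raise ValueError("gaze positions must be unique")
        if self.fov_deg <= 0:
            raise ValueError("fov_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].pixels.shape

    @property
    def px_per_deg(self) -> float:
        return self.shape[1] / self.fov_deg


@dataclass
class EllipseROI:
    """An elliptical annotation: center, semi-axes (a >= b), orientation.

    Tables store one row per ellipse with the header
    ``id,modality,cx,cy,a,b,angle_deg,label``.  Rows with a < b are
    normalized on construction by swapping the axes and rotating the
    major-axis angle by 90 deg (with a warning) so that ``a`` is always
    the major semi-axis.
    """

    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    angle_deg: float = 0.0
    label: str = ""
    modality: str = "gaze_dependent"
    id: str = ""

    def __post_init__(self) -> None:
        a, b = (float(v) for v in self.semi_axes_px)
        if b <= 0 or a <= 0:
            raise ValueError(f"ROI {self.id!r}: semi-axes must be positive")
        if a < b:
            warnings.warn(
                f"ROI {self.id!r}: a < b; swapping axes and rotating angle by 90",
                stacklevel=2,
            )
            a, b = b, a
            self.angle_deg = (self.angle_deg + 90.0) % 180.0
        self.semi_axes_px = (a, b)
        self.center_px = (float(self.center_px[0]), float(self.center_px[1]))
        if self.modality not in ROI_MODALITIES:
            raise ValueError(
                f"ROI {self.id!r}: modality {self.modality!r} not in {ROI_MODALITIES}"
            )


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG image as 2-D float; channels averaged to grayscale."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got {arr.shape}")
    return arr


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a float image, linearly mapped onto the full integer range.

    Undefined (NaN) pixels are written as 0; a constant image maps to
    mid-gray.  TIFF for 16-bit output, PNG or TIFF for 8-bit.
    """
    path = Path(path)
    image = np.asarray(image, dtype=float)
    defined = np.isfinite(image)
    if not defined.any():
        raise ValueError("cannot write an all-undefined image")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    vmax = np.float64(2**bit_depth - 1)
    lo, hi = image[defined].min(), image[defined].max()
    if hi > lo:
        scaled = (image - lo) / (hi - lo) * vmax
    else:
        scaled = np.full_like(image, vmax / 2)
    out = np.zeros(image.shape, dtype=np.uint8 if bit_depth == 8 else np.uint16)
    out[defined] = np.round(scaled[defined]).astype(out.dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_float_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write raw statistic values as 32-bit float TIFF (NaN preserved)."""
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def load_gaze_set(manifest_path: str | Path) -> GazeSet:
    """Load a gaze set from a JSON manifest.

    The manifest is an object with optional ``fov_deg`` and
    ``scale_um_per_px`` plus an ``images`` array of
    ``{"path", "gaze_x_deg", "gaze_y_deg", "id"}`` objects; paths are
    resolved relative to the manifest's directory.  Loading is
    deterministic and order-preserving.
    """
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    images = []
    for entry in spec["images"]:
        p = manifest_path.parent / entry["path"]
        images.append(
            GazeImage(
                pixels=read_image(p),
                gaze_deg=(entry["gaze_x_deg"], entry["gaze_y_deg"]),
                id=entry.get("id", Path(entry["path"]).stem),
            )
        )
    return GazeSet(
        images=images,
        fov_deg=float(spec.get("fov_deg", 4.0)),
        scale_um_per_px=float(spec.get("scale_um_per_px", 0.77)),
    )


def save_gaze_set(
    gaze_set: GazeSet, out_dir: str | Path, bit_depth: int = 16
) -> Path:
    """Write a gaze set as TIFFs plus a JSON manifest; returns manifest path.

    Note the on-disk images are integer-quantized to the requested bit
    depth, so a round trip preserves relative intensities (within
    quantization), not absolute float values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, im in enumerate(gaze_set.images):
        name = f"{im.id or f'img{k:02d}'}.tif"
        write_image(im.pixels, out_dir / name, bit_depth=bit_depth)
        entries.append(
            {
                "path": name,
                "gaze_x_deg": im.gaze_deg[0],
                "gaze_y_deg": im.gaze_deg[1],
                "id": im.id or f"img{k:02d}",
            }
        )
    manifest = {
        "fov_deg": gaze_set.fov_deg,
        "scale_um_per_px": gaze_set.scale_um_per_px,
        "images": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_roi_table(path: str | Path) -> list[EllipseROI]:
    """Read an ellipse ROI CSV (header ``id,modality,cx,cy,a,b,angle_deg,label``)."""
    path = Path(path)
    rois = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ROI_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(ROI_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for n, row in enumerate(reader, start=2):
            try:
                rois.append(
                    EllipseROI(
                        id=row["id"],
                        modality=row["modality"],
                        center_px=(float(row["cx"]), float(row["cy"])),
                        semi_axes_px=(float(row["a"]), float(row["b"])),
                        angle_deg=float(row["angle_deg"]),
                        label=row["label"],
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: bad ROI row at line {n}: {exc}") from exc
    return rois


def write_roi_table(rois: list[EllipseROI], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROI_HEADER)
        for r in rois:
            writer.writerow(
                [
                    r.id,
                    r.modality,
                    r.center_px[0],
                    r.center_px[1],
                    r.semi_axes_px[0],
                    r.semi_axes_px[1],
                    r.angle_deg,
                    r.label,
                ]
            )


def save_fused(
    fused, out_stem: str | Path, bit_depth: int = 16, raw: bool = True
) -> list[Path]:
    """Write a fused image: display TIFF + optional raw float TIFF + JSON sidecar.

    The display image is percentile-normalized (0.5-99.5% of defined
    pixels) before integer quantization, so single hot pixels cannot
    crush the rendering; raw statistic values go to a separate float
    TIFF untouched.
    """
    out_stem = Path(out_stem)
    out_stem.parent.mkdir(parents=True, exist_ok=True)
    vals = fused.defined_values()
    lo, hi = np.percentile(vals, [0.5, 99.5])
    display = np.clip(fused.values, lo, hi)
    paths = [out_stem.with_suffix(".tif")]
    write_image(display, paths[0], bit_depth=bit_depth)
    if raw:
        paths.append(out_stem.parent / (out_stem.name + "_raw.tif"))
        write_float_tiff(fused.values, paths[-1])
    sidecar = {
        "stat": fused.stat,
        "inverted": fused.inverted,
        "coverage_min": int(fused.coverage.min()),
        "coverage_max": int(fused.coverage.max()),
        "defined_fraction": float(np.mean(fused.defined_mask())),
        "display_percentiles": [float(lo), float(hi)],
    }
    paths.append(out_stem.with_suffix(".json"))
    paths[-1].write_text(json.dumps(sidecar, indent=2))
    return paths
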