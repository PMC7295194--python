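"""Stimulus rendering on a calibrated luminance raster.

The display is a uniform green field (15 cd/m^2, 15 x 15 deg) sampled at
0.4 arcmin per pixel -- roughly the size of a foveal cone.  Rendered
elements are a central fixation cross, a dark detection dot whose
diameter is the adaptively controlled stimulus level, and a thin black
ring used as an exogenous spatial cue.

Conventions (used everywhere):

* raster dimensions are odd, so fixation falls on a pixel center;
* the image origin is the raster center; x increases rightward and y
  upward in *field* coordinates;
* locations are labeled by *retinal* quadrant; the retina-to-field
  mapping (which mirrors left/right through the eye's optics) is
  isolated in :func:`quadrant_to_field_direction`;
* painting uses a binary pixel-center inclusion test (no antialiasing),
  which keeps rendering deterministic and pixel counts exactly
  checkable; a dot smaller than one pixel paints the single pixel
  nearest its center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import LOCATIONS

__all__ = [
    "StimulusError",
    "DisplayGeometry",
    "StimulusImage",
    "TargetSpec",
    "CueSpec",
    "quadrant_to_field_direction",
    "field_direction_to_quadrant",
    "render_background",
    "render_target",
    "render_cue",
    "render_fixation",
    "image_to_png",
    "save_frames",
]


class StimulusError(ValueError):
    """Invalid stimulus geometry or rendering request."""


@dataclass(frozen=True)
class DisplayGeometry:
    """Calibrated display raster and task geometry."""

    field_width_deg: float = 15.0
    field_height_deg: float = 15.0
    pixel_scale_arcmin: float = 0.4
    background_cd_m2: float = 15.0
    eccentricity_deg: float = 5.0
    eye: str = "right"

    def __post_init__(self) -> None:
        if self.pixel_scale_arcmin <= 0:
            raise StimulusError("pixel_scale_arcmin must be > 0")
        if self.field_width_deg <= 0 or self.field_height_deg <= 0:
            raise StimulusError("field dimensions must be > 0")
        if self.background_cd_m2 < 0:
            raise StimulusError("background luminance must be >= 0")
        if not 0 < 2 * self.eccentricity_deg < min(
            self.field_width_deg, self.field_height_deg
        ):
            raise StimulusError("eccentricity does not fit inside the field")
        if self.eye not in ("right", "left"):
            raise StimulusError("eye must be 'right' or 'left'")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols); forced odd so fixation is a pixel center."""
        ny = round(self.field_height_deg * 60.0 / self.pixel_scale_arcmin)
        nx = round(self.field_width_deg * 60.0 / self.pixel_scale_arcmin)
        return (ny + 1 - ny % 2, nx + 1 - nx % 2)


@dataclass(frozen=True)
class StimulusImage:
    """Luminance raster in cd/m^2 with its angular pixel scale."""

    luminance_grid: np.ndarray
    pixel_scale_arcmin: float

    def __post_init__(self) -> None:
        if np.any(self.luminance_grid < 0):
            raise StimulusError("luminances must be >= 0")


@dataclass(frozen=True)
class TargetSpec:
    """Dark detection dot; its diameter is the adaptive stimulus level."""

    diameter_arcmin: float
    location: str
    luminance_cd_m2: float = 0.5
    onset_ms: float = 0.0
    duration_ms: float = 33.0

    def __post_init__(self) -> None:
        if self.diameter_arcmin <= 0:
            raise StimulusError("diameter must be > 0")
        if self.location not in LOCATIONS:
            raise StimulusError(f"unknown quadrant {self.location!r}")


@dataclass(frozen=True)
class CueSpec:
    """Thin black ring flashed at a candidate target location."""

    location: str
    ring_diameter_deg: float = 2.5
    thickness_arcmin: float = 1.25
    luminance_cd_m2: float = 0.0
    duration_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise StimulusError(f"unknown quadrant {self.location!r}")
        if not 0 < self.thickness_arcmin <= self.ring_diameter_deg * 60.0 / 2:
            raise StimulusError("thickness must be positive and at most the ring radius")


# Retinal-to-field mapping.  The eye's optics invert the image: the
# nasal retina views the temporal field and the superior retina views
# the inferior field.  For a right eye the temporal field is rightward
# (+x); for a left eye it is leftward.
_FIELD_DIRECTION = {
    "right": {
        "nasal": (1.0, 0.0),
        "temporal": (-1.0, 0.0),
        "superior": (0.0, -1.0),
        "inferior": (0.0, 1.0),
    },
    "left": {
        "nasal": (-1.0, 0.0),
        "temporal": (1.0, 0.0),
        "superior": (0.0, -1.0),
        "inferior": (0.0, 1.0),
    },
}


def quadrant_to_field_direction(quadrant: str, eye: str = "right") -> tuple[float, float]:
    """Unit (x, y) field direction for a retinal quadrant label."""
    try:
        return _FIELD_DIRECTION[eye][quadrant]
    except KeyError as exc:
        raise StimulusError(f"unknown eye/quadrant: {eye!r}/{quadrant!r}") from exc


def field_direction_to_quadrant(direction: tuple[float, float], eye: str = "right") -> str:
    """Inverse of :func:`quadrant_to_field_direction` (label round-trip)."""
    for quadrant, vec in _FIELD_DIRECTION[eye].items():
        if np.allclose(vec, direction):
            return quadrant
    raise StimulusError(f"direction {direction} is not a cardinal field direction")


def _coords(geometry: DisplayGeometry) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = geometry.shape
    s = geometry.pixel_scale_arcmin
    x = (np.arange(nx) - nx // 2) * s
    y = (ny // 2 - np.arange(ny)) * s
    return x, y


def _center_arcmin(location: str, geometry: DisplayGeometry) -> tuple[float, float]:
    dx, dy = quadrant_to_field_direction(location, geometry.eye)
    ecc = geometry.eccentricity_deg * 60.0
    return dx * ecc, dy * ecc


def render_background(geometry: DisplayGeometry) -> StimulusImage:
    """Uniform field at the background luminance."""
    return StimulusImage(
        np.full(geometry.shape, float(geometry.background_cd_m2)),
        geometry.pixel_scale_arcmin,
    )


def render_target(
    spec: TargetSpec, geometry: DisplayGeometry, base: StimulusImage
) -> StimulusImage:
    """Paint the dark dot at its quadrant's isoeccentric position."""
    cx, cy = _center_arcmin(spec.location, geometry)
    r = spec.diameter_arcmin / 2.0
    half_w = geometry.field_width_deg * 60.0 / 2.0
    half_h = geometry.field_height_deg * 60.0 / 2.0
    if abs(cx) + r > half_w or abs(cy) + r > half_h:
        raise StimulusError("target does not fit inside the field")
    x, y = _coords(geometry)
    dist2 = (x - cx)[None, :] ** 2 + (y - cy)[:, None] ** 2
    mask = dist2 <= r * r
    grid = base.luminance_grid.copy()
    if mask.any():
        grid[mask] = spec.luminance_cd_m2
    else:  # sub-pixel dot: paint the pixel nearest the dot center
        ny, nx = geometry.shape
        s = geometry.pixel_scale_arcmin
        grid[ny // 2 - round(cy / s), nx // 2 + round(cx / s)] = spec.luminance_cd_m2
    return StimulusImage(grid, base.pixel_scale_arcmin)


def render_cue(
    spec: CueSpec, geometry: DisplayGeometry, base: StimulusImage
) -> StimulusImage:
    """Paint the cue annulus centered on its quadrant's target position.

    The ring's outer radius is half its nominal diameter; the annulus
    extends inward by the ring thickness, so a large thin ring leaves a
    wide protected zone around the (much smaller) detection dot.
    """
    cx, cy = _center_arcmin(spec.location, geometry)
    outer = spec.ring_diameter_deg * 60.0 / 2.0
    inner = max(outer - spec.thickness_arcmin, 0.0)
    half_w = geometry.field_width_deg * 60.0 / 2.0
    half_h = geometry.field_height_deg * 60.0 / 2.0
    if abs(cx) + outer > half_w or abs(cy) + outer > half_h:
        raise StimulusError("cue ring does not fit inside the field")
    x, y = _coords(geometry)
    dist2 = (x - cx)[None, :] ** 2 + (y - cy)[:, None] ** 2
    mask = (dist2 <= outer * outer) & (dist2 >= inner * inner)
    grid = base.luminance_grid.copy()
    grid[mask] = spec.luminance_cd_m2
    return StimulusImage(grid, base.pixel_scale_arcmin)


def render_fixation(
    geometry: DisplayGeometry,
    base: StimulusImage,
    arm_length_deg: float = 0.5,
    thickness_arcmin: float = 1.25,
    luminance_cd_m2: float = 0.0,
) -> StimulusImage:
    """Paint the central fixation cross (two orthogonal bars)."""
    half = arm_length_deg * 60.0 / 2.0
    t = thickness_arcmin / 2.0
    x, y = _coords(geometry)
    ax = np.abs(x)[None, :]
    ay = np.abs(y)[:, None]
    mask = ((ax <= half) & (ay <= t)) | ((ay <= half) & (ax <= t))
    grid = base.luminance_grid.copy()
    grid[mask] = luminance_cd_m2
    return StimulusImage(grid, base.pixel_scale_arcmin)


def image_to_png(image: StimulusImage, path, v_max: float | None = None) -> None:
    """Export a luminance raster as an 8-bit grayscale PNG."""
    from PIL import Image

    grid = image.luminance_grid
    scale = v_max if v_max is not None else max(grid.max(), 1e-12)
    scaled = np.clip(255.0 * grid / scale, 0, 255).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)


def save_frames(frames, out_dir) -> None:
    """Write a stimulus sequence as numbered PNGs plus a CSV manifest.

    ``frames`` is an iterable of ``(label, image, onset_ms, duration_ms)``.
    """
    import csv
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v_max = max(f[1].luminance_grid.max() for f in frames)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "onset_ms", "duration_ms", "content"])
        for i, (label, image, onset, duration) in enumerate(frames):
            name = f"frame_{i:03d}.png"
            image_to_png(image, out / name, v_max=v_max)
            writer.writerow([name, onset, duration, label])
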