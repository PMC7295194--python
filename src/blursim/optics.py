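"""Fourier-optics simulation of defocus blur.

Defocus is specified as the coefficient of the ANSI-normalized Zernike
defocus polynomial ``Z_2^0 = sqrt(3) * (2 rho^2 - 1)``; with this
normalization the coefficient equals the RMS wavefront error it
contributes, which makes "n waves of RMS" an unambiguous amount of
aberration.  The point spread function (PSF) of an eye with pupil
diameter ``D`` viewing monochromatic light of wavelength ``lambda`` is
computed as the squared modulus of the Fourier transform of the
generalized pupil function

    P(rho, theta) = A(rho) * exp(i * 2*pi/lambda * W(rho)),

where ``A`` is a binary disc and ``W = c * sqrt(3) * (2 rho^2 - 1)`` is
the wavefront error in length units.  Blurred stimuli are produced by
convolving a calibrated luminance raster with the energy-normalized PSF
resampled onto the raster's pixel grid.

Only monochromatic defocus is modeled; higher-order aberrations,
polychromatic PSFs and Stiles-Crawford apodization are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftshift, ifftshift
from scipy.signal import fftconvolve

from .stimuli import StimulusImage

__all__ = [
    "OpticsError",
    "WavefrontSpec",
    "PupilFunction",
    "PsfKernel",
    "defocus_rms_to_diopters",
    "diopters_to_defocus_rms",
    "build_pupil_function",
    "pupil_to_psf",
    "compute_psf",
    "strehl_ratio",
    "resample_psf",
    "convolve_stimulus",
    "psf_to_csv",
    "psf_from_csv",
    "psf_to_png",
]

ARCMIN_PER_RADIAN = 60.0 * 180.0 / np.pi
_SQRT3 = np.sqrt(3.0)


class OpticsError(ValueError):
    """Invalid optical specification or operation."""


@dataclass(frozen=True)
class WavefrontSpec:
    """Defocus aberration to simulate.

    Parameters
    ----------
    rms_wfe_um
        RMS wavefront error of the Zernike defocus term, in micrometres.
        No other aberration terms are modeled.
    wavelength_nm
        Monochromatic wavelength in nanometres (default 550, mid-green).
    pupil_diameter_mm
        Pupil diameter in millimetres over which the wavefront is defined.
    """

    rms_wfe_um: float
    wavelength_nm: float = 550.0
    pupil_diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.rms_wfe_um < 0:
            raise OpticsError("rms_wfe_um must be >= 0")
        if self.wavelength_nm <= 0:
            raise OpticsError("wavelength_nm must be > 0")
        if self.pupil_diameter_mm <= 0:
            raise OpticsError("pupil_diameter_mm must be > 0")


@dataclass(frozen=True)
class PupilFunction:
    """Complex generalized pupil function on a zero-padded square grid."""

    amplitude_phase_grid: np.ndarray
    grid_size: int
    pupil_samples: int


@dataclass(frozen=True)
class PsfKernel:
    """Energy-normalized PSF intensity raster with angular pixel scale."""

    intensity_grid: np.ndarray
    pixel_scale_arcmin: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if np.any(self.intensity_grid < 0):
            raise OpticsError("PSF intensities must be non-negative")
        if abs(self.intensity_grid.sum() - 1.0) > 1e-9:
            raise OpticsError("PSF must be energy-normalized to sum 1")


def defocus_rms_to_diopters(rms_wfe_um: float, pupil_diameter_mm: float) -> float:
    """Spherical-equivalent defocus ``M = 4*sqrt(3)*c / r**2`` in diopters.

    ``c`` is the Zernike defocus RMS coefficient in micrometres and ``r``
    the pupil radius in millimetres; the micrometre/millimetre unit pair
    makes the result come out directly in diopters.
    """
    if pupil_diameter_mm <= 0:
        raise OpticsError("pupil_diameter_mm must be > 0")
    if rms_wfe_um < 0:
        raise OpticsError("rms_wfe_um must be >= 0")
    r = pupil_diameter_mm / 2.0
    return 4.0 * _SQRT3 * rms_wfe_um / r**2


def diopters_to_defocus_rms(defocus_d: float, pupil_diameter_mm: float) -> float:
    """Inverse of :func:`defocus_rms_to_diopters` (micrometres of RMS)."""
    if pupil_diameter_mm <= 0:
        raise OpticsError("pupil_diameter_mm must be > 0")
    r = pupil_diameter_mm / 2.0
    return defocus_d * r**2 / (4.0 * _SQRT3)


def build_pupil_function(
    spec: WavefrontSpec,
    pupil_samples: int = 128,
    grid_size: int | None = None,
) -> PupilFunction:
    """Sample the generalized pupil function on a zero-padded grid.

    The pupil disc spans ``pupil_samples`` samples of a ``grid_size``
    square grid (default padding factor 4); padding below 2x the pupil
    is refused because the resulting PSF would be undersampled.
    """
    if grid_size is None:
        grid_size = 4 * pupil_samples
    if grid_size < 2 * pupil_samples:
        raise OpticsError(
            f"grid_size ({grid_size}) must be >= 2 * pupil_samples "
            f"({pupil_samples}) to avoid PSF aliasing"
        )
    idx = np.arange(grid_size) - grid_size // 2
    # normalized pupil coordinate: rho = 1 at the pupil edge
    rho_1d = idx * (2.0 / pupil_samples)
    rho2 = rho_1d[None, :] ** 2 + rho_1d[:, None] ** 2
    mask = rho2 <= 1.0 + 1e-12
    lam_um = spec.wavelength_nm * 1e-3
    phase = (2.0 * np.pi / lam_um) * spec.rms_wfe_um * _SQRT3 * (2.0 * rho2 - 1.0)
    grid = np.where(mask, np.exp(1j * phase), 0.0 + 0.0j)
    return PupilFunction(grid, grid_size, pupil_samples)


def pupil_to_psf(pupil: PupilFunction, spec: WavefrontSpec) -> PsfKernel:
    """PSF intensity as ``|FFT(pupil)|**2``, energy-normalized.

    The angular pixel scale of the PSF plane follows from the discrete
    Fourier pairing: ``pixel = lambda / (grid_size * delta_pupil)``
    radians, where ``delta_pupil`` is the pupil-plane sample spacing.
    """
    field = fftshift(fft2(ifftshift(pupil.amplitude_phase_grid)))
    intensity = np.abs(field) ** 2
    total = intensity.sum()
    if total <= 0:
        raise OpticsError("empty pupil function")
    intensity /= total
    delta_pupil_m = spec.pupil_diameter_mm * 1e-3 / pupil.pupil_samples
    pixel_rad = spec.wavelength_nm * 1e-9 / (pupil.grid_size * delta_pupil_m)
    return PsfKernel(intensity, pixel_rad * ARCMIN_PER_RADIAN, spec.wavelength_nm)


def compute_psf(
    spec: WavefrontSpec,
    pupil_samples: int = 128,
    grid_size: int | None = None,
) -> PsfKernel:
    """Convenience: pupil construction followed by the PSF transform."""
    return pupil_to_psf(build_pupil_function(spec, pupil_samples, grid_size), spec)


def strehl_ratio(
    spec: WavefrontSpec,
    pupil_samples: int = 128,
    grid_size: int | None = None,
) -> float:
    """Peak PSF intensity relative to the diffraction-limited peak.

    Computed at identical sampling for the aberrated and zero-aberration
    pupils so discretization effects cancel.
    """
    aberrated = compute_psf(spec, pupil_samples, grid_size)
    perfect = compute_psf(
        WavefrontSpec(0.0, spec.wavelength_nm, spec.pupil_diameter_mm),
        pupil_samples,
        grid_size,
    )
    return float(aberrated.intensity_grid.max() / perfect.intensity_grid.max())


def _overlap_matrix(out_edges: np.ndarray, in_edges: np.ndarray, in_width: float) -> np.ndarray:
    lo = np.maximum(out_edges[:-1, None], in_edges[None, :-1])
    hi = np.minimum(out_edges[1:, None], in_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None) / in_width


def resample_psf(psf: PsfKernel, pixel_scale_arcmin: float) -> PsfKernel:
    """Area-preserving resampling of a PSF onto a coarser/finer pixel grid.

    Each output pixel receives the input energy in proportion to the
    geometric overlap of pixel footprints, so the kernel's energy and
    its center of mass are preserved.  Output dimensions are odd so the
    kernel has a central pixel.
    """
    if pixel_scale_arcmin <= 0:
        raise OpticsError("pixel_scale_arcmin must be > 0")
    s_in = psf.pixel_scale_arcmin
    if abs(s_in - pixel_scale_arcmin) < 1e-12 * max(s_in, pixel_scale_arcmin):
        return psf
    n = psf.intensity_grid.shape[0]
    extent = n * s_in
    n_out = int(np.ceil(extent / pixel_scale_arcmin))
    if n_out % 2 == 0:
        n_out += 1
    # pixel centers sit at (i - n//2) * scale, matching the FFT origin bin
    in_edges = (np.arange(n + 1) - n // 2 - 0.5) * s_in
    out_edges = (np.arange(n_out + 1) - n_out // 2 - 0.5) * pixel_scale_arcmin
    a = _overlap_matrix(out_edges, in_edges, s_in)
    out = a @ psf.intensity_grid @ a.T
    out = np.clip(out, 0.0, None)
    out /= out.sum()
    return PsfKernel(out, pixel_scale_arcmin, psf.wavelength_nm)


def _crop_kernel(kernel: np.ndarray, keep: float = 1.0 - 1e-8) -> np.ndarray:
    """Smallest centered odd square holding at least ``keep`` of the energy."""
    n = kernel.shape[0]
    c = n // 2
    total = kernel.sum()
    for h in range(c + 1):
        block = kernel[c - h : c + h + 1, c - h : c + h + 1]
        if block.sum() >= keep * total:
            return block / block.sum()
    return kernel / total


def convolve_stimulus(
    image: StimulusImage,
    psf: PsfKernel,
    background: float | None = None,
) -> StimulusImage:
    """Blur a luminance raster by convolution with a PSF.

    The PSF is resampled (area-preserving) onto the image's pixel grid
    and cropped to its significant support.  The image is padded with
    the background luminance before convolution -- the stimulus sits on
    an extended uniform field, so this boundary rule is physically
    correct and preserves the mean luminance.  When ``background`` is
    not given it is taken as the median border luminance.
    """
    kern = resample_psf(psf, image.pixel_scale_arcmin)
    k = _crop_kernel(kern.intensity_grid)
    grid = image.luminance_grid
    if k.shape[0] > grid.shape[0] or k.shape[1] > grid.shape[1]:
        raise OpticsError(
            f"PSF support {k.shape} is wider than the image {grid.shape}"
        )
    if background is None:
        border = np.concatenate([grid[0], grid[-1], grid[:, 0], grid[:, -1]])
        background = float(np.median(border))
    pad = k.shape[0] // 2
    padded = np.pad(grid, pad, constant_values=background)
    out = fftconvolve(padded, k, mode="valid")
    np.clip(out, grid.min(), grid.max(), out=out)
    return StimulusImage(out, image.pixel_scale_arcmin)


def psf_to_csv(psf: PsfKernel, path) -> None:
    """Write the raw intensity grid as CSV (round-trips bit-faithfully)."""
    header = (
        f"pixel_scale_arcmin={psf.pixel_scale_arcmin!r} "
        f"wavelength_nm={psf.wavelength_nm!r}"
    )
    np.savetxt(path, psf.intensity_grid, delimiter=",", fmt="%.17e", header=header)


def psf_from_csv(path) -> PsfKernel:
    with open(path) as fh:
        first = fh.readline()
    meta = dict(
        item.split("=") for item in first.lstrip("# ").strip().split() if "=" in item
    )
    grid = np.loadtxt(path, delimiter=",")
    return PsfKernel(
        grid,
        float(meta["pixel_scale_arcmin"]),
        float(meta["wavelength_nm"]),
    )


def psf_to_png(psf: PsfKernel, path) -> None:
    """8-bit visualization of the PSF (peak-normalized, linear scale)."""
    from PIL import Image

    grid = psf.intensity_grid
    scaled = (255.0 * grid / grid.max()).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)
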