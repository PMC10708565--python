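"""Synthetic paired crushed/full-form spectral datasets with known truth.

Each sample's crushed-form spectrum is a smooth baseline minus Gaussian
absorption dips (centres near known NIR absorption bands) whose depths are
affine in the sample's reference value, plus per-sample multiplicative/
additive scatter and noise. The full-form spectrum is the clean crushed
spectrum pushed through a smooth band-wise affine distortion (the "form
map"), then given larger scatter and noise — so scatter correction can fix
the per-sample effects but only calibration transfer can undo the form map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CRUSHED, FULL, Dataset, SpectraSet
from .errors import ParameterError
from .hsi_io import CalibrationFrames, HSICube

__all__ = ["FixtureConfig", "generate_dataset_pair", "generate_cube"]

_DEFAULT_PEAKS = (944.0, 980.0, 1076.0, 1186.0, 1264.0, 1455.0)


@dataclass
class FixtureConfig:
    """Generative parameters for the paired-form fixture."""

    n_samples: int = 100
    n_bands: int = 256
    wavelength_range: tuple[float, float] = (885.0, 1735.0)
    peak_centers: tuple[float, ...] = _DEFAULT_PEAKS
    tvc_range: tuple[float, float] = (2.1347, 3.8808)
    cs_noise_sd: float = 0.15
    fs_noise_sd: float = 0.45
    cs_scatter_slope_sd: float = 0.04
    cs_scatter_offset_sd: float = 1.0
    fs_scatter_slope_sd: float = 0.10
    fs_scatter_offset_sd: float = 2.5
    form_gain_amplitude: float = 0.3  # band-wise gain in [1-a, 1+a]
    form_offset_amplitude: float = 3.0  # band-wise offset in +/- this many % reflectance
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.wavelength_range
        if self.n_samples < 2 or self.n_bands < 2:
            raise ParameterError("need at least 2 samples and 2 bands")
        if not lo < hi:
            raise ParameterError("wavelength_range must be increasing")
        if any(not lo <= c <= hi for c in self.peak_centers):
            raise ParameterError("peak centers must lie inside the wavelength range")
        if not self.tvc_range[0] < self.tvc_range[1]:
            raise ParameterError("tvc_range must be increasing")
        if self.fs_noise_sd < self.cs_noise_sd:
            raise ParameterError("full-form noise must be >= crushed-form noise")
        if min(self.cs_noise_sd, self.fs_noise_sd) < 0:
            raise ParameterError("noise standard deviations must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


def _baseline(wl: np.ndarray) -> np.ndarray:
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    return 45.0 + 8.0 * t + 5.0 * np.sin(2.0 * np.pi * t)


def _form_map(config: FixtureConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Smooth band-wise affine distortion: per-band (gain, offset)."""
    t = np.linspace(0.0, 1.0, config.n_bands)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    gain = 1.0 + config.form_gain_amplitude * np.sin(2.0 * np.pi * 1.5 * t + phases[0])
    offset = config.form_offset_amplitude * np.sin(2.0 * np.pi * 1.0 * t + phases[1])
    return gain, offset


def generate_dataset_pair(config: FixtureConfig | None = None) -> tuple[Dataset, Dataset, dict]:
    """Paired crushed/full datasets sharing sample ids and reference values.

    Returns ``(cs, fs, truth)`` where ``truth`` holds the form map, the peak
    response coefficients and the clean (scatter- and noise-free) spectra.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    n, b = config.n_samples, config.n_bands

    tvc = rng.uniform(*config.tvc_range, size=n)
    tvc_mid = float(np.mean(config.tvc_range))

    centers = np.asarray(config.peak_centers)
    widths = rng.uniform(15.0, 35.0, size=centers.size)
    base_depth = rng.uniform(3.0, 8.0, size=centers.size)
    # signed response of each dip depth to the reference value
    signs = np.where(np.arange(centers.size) % 2 == 0, 1.0, -1.0)
    depth_slope = signs * rng.uniform(1.5, 3.0, size=centers.size)
    shapes = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)

    depths = base_depth[None, :] + depth_slope[None, :] * (tvc - tvc_mid)[:, None]
    cs_clean = _baseline(wl)[None, :] - depths @ shapes

    gain, offset = _form_map(config, rng)
    fs_clean = cs_clean * gain[None, :] + offset[None, :]

    def scatter_and_noise(clean: np.ndarray, slope_sd: float, offset_sd: float, noise_sd: float) -> np.ndarray:
        a = rng.normal(1.0, slope_sd, size=n)
        bshift = rng.normal(0.0, offset_sd, size=n)
        noisy = clean * a[:, None] + bshift[:, None]
        if noise_sd > 0:
            noisy = noisy + rng.normal(0.0, noise_sd, size=(n, b))
        return noisy

    cs_X = scatter_and_noise(cs_clean, config.cs_scatter_slope_sd, config.cs_scatter_offset_sd, config.cs_noise_sd)
    fs_X = scatter_and_noise(fs_clean, config.fs_scatter_slope_sd, config.fs_scatter_offset_sd, config.fs_noise_sd)

    ids = [f"S{i:03d}" for i in range(n)]
    cs = Dataset(SpectraSet(cs_X, wl, ids, form=CRUSHED), tvc)
    fs = Dataset(SpectraSet(fs_X, wl, ids, form=FULL), tvc)
    truth = {
        "form_gain": gain,
        "form_offset": offset,
        "peak_centers": centers,
        "peak_widths": widths,
        "peak_base_depth": base_depth,
        "peak_depth_slope": depth_slope,
        "tvc": tvc,
        "cs_clean": cs_clean,
        "fs_clean": fs_clean,
    }
    return cs, fs, truth


@dataclass
class CubeLayout:
    """Spatial layout of the synthetic cube."""

    rows: int = 20
    cols: int = 20
    margin: int = 3  # background border width in pixels
    white_level: float = 1000.0
    dark_level: float = 100.0
    noise_sd: float = 0.0  # pixel noise in % reflectance

    foreground: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.rows <= 2 * self.margin or self.cols <= 2 * self.margin:
            raise ParameterError("cube too small for the requested background margin")
        if self.white_level <= self.dark_level:
            raise ParameterError("white level must exceed dark level")
        fg = np.zeros((self.rows, self.cols), dtype=bool)
        fg[self.margin : self.rows - self.margin, self.margin : self.cols - self.margin] = True
        self.foreground = fg


def generate_cube(
    config: FixtureConfig,
    sample_spectrum: np.ndarray,
    layout: CubeLayout | None = None,
    seed: int = 0,
) -> tuple[HSICube, CalibrationFrames, np.ndarray]:
    """Encode a sample spectrum into a raw-count cube with reference frames.

    Foreground pixels carry ``sample_spectrum`` (plus optional pixel noise)
    re-encoded as counts consistent with the emitted white/dark frames, so
    reflectance calibration followed by an ROI mean recovers the spectrum.
    Returns ``(cube, frames, foreground_mask)``.
    """
    layout = layout or CubeLayout()
    spectrum = np.ravel(np.asarray(sample_spectrum, dtype=float))
    if spectrum.size != config.n_bands:
        raise ParameterError(
            f"sample spectrum has {spectrum.size} bands, config says {config.n_bands}"
        )
    rng = np.random.default_rng(seed)
    rows, cols = layout.rows, layout.cols
    refl = np.zeros((rows, cols, config.n_bands))
    refl[layout.foreground] = spectrum
    if layout.noise_sd > 0:
        noise = rng.normal(0.0, layout.noise_sd, size=refl.shape)
        refl = np.where(layout.foreground[:, :, None], refl + noise, refl)
    white = np.full((rows, cols), layout.white_level)
    dark = np.full((rows, cols), layout.dark_level)
    raw = dark[:, :, None] + refl / 100.0 * (white - dark)[:, :, None]
    cube = HSICube(data=raw, wavelengths=config.wavelengths, meta={"synthetic": True})
    return cube, CalibrationFrames(white=white, dark=dark), layout.foreground.copy()
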