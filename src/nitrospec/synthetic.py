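"""Synthetic leaf-reflectance generator for the four nitrogen-treatment classes.

The generator emulates the statistical structure the downstream analysis
assumes for cucumber leaves sampled the day before (D0) and on three
consecutive days after (D1–D3) an excess-nitrogen application:

* a smooth leaf-like base spectrum — low visible reflectance with a green
  bump, a red-edge rise near 700–740 nm, a NIR plateau and a water dip;
* class-dependent Gaussian absorption features at a few informative bands
  (defaults 723, 781, 901 nm), so a wavelength selector has a known ground
  truth to recover;
* per-spectrum multiplicative scatter (random gain and offset), which
  multiplicative scatter correction is later expected to remove;
* additive Gaussian noise, spectrally correlated over a few nanometres the
  way detector and illumination noise is;
* a D1/D3 confusability structure: newly grown leaves on day three make the
  D3 population revert toward earlier days, modelled by blending the D3
  class mean toward the D1 and D0 means (plus a weak D3-specific feature,
  so the class geometry stays full rank).

Everything is driven by :class:`GeneratorConfig`; the same config and seed
produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataset import REFLECTANCE, SpectralDataset

__all__ = ["Band", "GeneratorConfig", "generate_dataset", "class_mean_spectrum",
           "base_reflectance"]


@dataclass(frozen=True)
class Band:
    """An informative absorption band.

    ``depths`` gives, per class (in ``class_names`` order), the maximum
    reflectance decrease at the band centre; the feature decays as a
    Gaussian of standard deviation ``width`` nm.
    """

    center: float
    width: float
    depths: tuple[float, ...]


def _default_bands() -> tuple[Band, ...]:
    # Depth patterns chosen so that every centre carries class information
    # the other two cannot replace: 723 nm is the only band separating D0
    # from D1 (and hence from the D3 blend), 781 nm the only band where D2
    # and D3 differ, and 901 nm the only band giving D3 away against D1.
    # D3's entries are its own small features applied on top of the
    # d1_d3_overlap blend.
    return (
        Band(723.0, 4.0, (0.0, 0.0390, 0.0362, 0.0)),
        Band(781.0, 4.0, (0.0, 0.0000, 0.0173, 0.0)),
        Band(901.0, 4.0, (0.0, 0.0000, 0.0110, 0.0110)),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-spectra generator.

    Defaults describe the nominal study conditions: a 400–1100 nm grid at
    2 nm, four classes D0–D3, three informative bands, mild scatter and
    noise, and a strong D3→D1 reversion (``d1_d3_overlap = 0.927``).
    """

    n_per_class: int = 100
    wavelength_start: float = 400.0
    wavelength_stop: float = 1100.0
    wavelength_step: float = 2.0
    class_names: tuple[str, ...] = ("D0", "D1", "D2", "D3")
    informative_bands: tuple[Band, ...] = field(default_factory=_default_bands)
    scatter_gain_sd: float = 0.01
    scatter_offset_sd: float = 0.002
    noise_sd: float = 0.0025
    noise_correlation_nm: float = 4.0
    d1_d3_overlap: float | None = 0.927
    seed: int = 0

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start)
                      / self.wavelength_step)) + 1
        grid = self.wavelength_start + self.wavelength_step * np.arange(n)
        return grid[grid <= self.wavelength_stop + 1e-9]

    def validate(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if not (400.0 <= self.wavelength_start < self.wavelength_stop <= 1100.0):
            raise ValueError("wavelength range must lie within [400, 1100] nm")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be positive")
        for sd in (self.scatter_gain_sd, self.scatter_offset_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.noise_correlation_nm < 0:
            raise ValueError("noise_correlation_nm must be >= 0")
        if self.d1_d3_overlap is not None and not 0.0 <= self.d1_d3_overlap <= 1.0:
            raise ValueError("d1_d3_overlap must lie in [0, 1]")
        lo, hi = self.wavelength_start, self.wavelength_stop
        for band in self.informative_bands:
            if not lo <= band.center <= hi:
                raise ValueError(
                    f"band center {band.center} nm outside grid [{lo}, {hi}]"
                )
            if band.width <= 0:
                raise ValueError("band width must be positive")
            if len(band.depths) != len(self.class_names):
                raise ValueError(
                    f"band at {band.center} nm has {len(band.depths)} depths "
                    f"for {len(self.class_names)} classes"
                )


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int],
                      sd: float, corr_bands: float) -> np.ndarray:
    """Gaussian noise with per-band sd ``sd``, smooth across wavelengths."""
    white = rng.standard_normal(shape)
    if sd == 0.0 or shape[0] == 0:
        return np.zeros(shape)
    if corr_bands <= 0:
        return sd * white
    smooth = gaussian_filter1d(white, sigma=corr_bands / 2.0, axis=1,
                               mode="reflect")
    # rescale so the marginal per-band standard deviation is exactly sd
    kernel_norm = np.sqrt(np.sum(_gaussian_kernel(corr_bands / 2.0) ** 2))
    return sd * smooth / kernel_norm


def _gaussian_kernel(sigma: float) -> np.ndarray:
    radius = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def base_reflectance(wavelengths: np.ndarray) -> np.ndarray:
    """Nominal healthy-leaf reflectance on the given grid (dimensionless)."""
    w = np.asarray(wavelengths, dtype=float)
    green_bump = 0.03 * np.exp(-((w - 550.0) ** 2) / (2 * 20.0 ** 2))
    red_edge = 0.75 / (1.0 + np.exp(-(w - 715.0) / 18.0))
    water_dip = -0.06 * np.exp(-((w - 970.0) ** 2) / (2 * 25.0 ** 2))
    return 0.05 + green_bump + red_edge + water_dip


def class_mean_spectrum(config: GeneratorConfig, class_index: int,
                        wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Closed-form noise-free mean spectrum of one class.

    The mean is the base curve minus the class's Gaussian absorption
    features.  When ``d1_d3_overlap`` is set and there are at least four
    classes, class index 3 reverts toward the earlier days: its mean is the
    convex blend ``overlap * mean(class 1) + (1 - overlap) * mean(class 0)``
    minus class 3's own (small) absorption features — the newly grown
    leaves of the last sampling day mostly resemble D1/D0 but keep a weak
    signature of their own.
    """
    if wavelengths is None:
        wavelengths = config.wavelength_grid()
    w = np.asarray(wavelengths, dtype=float)
    if (config.d1_d3_overlap is not None and class_index == 3
            and len(config.class_names) >= 4):
        a = config.d1_d3_overlap
        mean = (a * class_mean_spectrum(config, 1, w)
                + (1.0 - a) * class_mean_spectrum(config, 0, w))
    else:
        mean = base_reflectance(w)
    for band in config.informative_bands:
        profile = np.exp(-((w - band.center) ** 2) / (2 * band.width ** 2))
        mean = mean - band.depths[class_index] * profile
    return mean


def generate_dataset(config: GeneratorConfig) -> SpectralDataset:
    """Draw a labelled reflectance dataset from the generator model.

    Each row is ``mean_class(λ) * gain + offset + noise`` with
    ``gain ~ N(1, scatter_gain_sd)``, ``offset ~ N(0, scatter_offset_sd)``
    and Gaussian noise of per-band standard deviation ``noise_sd``,
    spectrally correlated over ``noise_correlation_nm`` (detector and
    illumination noise is smooth across neighbouring bands; set the
    correlation length to 0 for white noise).  Values are clipped into
    (0, 1].  Rows are class-major in ``class_names`` order.
    """
    config.validate()
    grid = config.wavelength_grid()
    rng = np.random.default_rng(config.seed)
    n_classes = len(config.class_names)
    rows = np.empty((config.n_per_class * n_classes, grid.size))
    labels = np.empty(rows.shape[0], dtype=object)
    for ci, name in enumerate(config.class_names):
        mean = class_mean_spectrum(config, ci, grid)
        sl = slice(ci * config.n_per_class, (ci + 1) * config.n_per_class)
        gain = 1.0 + config.scatter_gain_sd * rng.standard_normal(
            (config.n_per_class, 1))
        offset = config.scatter_offset_sd * rng.standard_normal(
            (config.n_per_class, 1))
        noise = _correlated_noise(rng, (config.n_per_class, grid.size),
                                  config.noise_sd,
                                  config.noise_correlation_nm
                                  / config.wavelength_step)
        rows[sl] = mean[None, :] * gain + offset + noise
        labels[sl] = name
    np.clip(rows, 1e-6, 1.0, out=rows)
    return SpectralDataset(wavelengths=grid, values=rows, labels=labels,
                           domain_tag=REFLECTANCE)
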