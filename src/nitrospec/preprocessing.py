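"""Spectral preprocessing: absorbance transform, MSC, median smoothing.

The fixed pipeline order is reflectance → absorbance (A = log10(1/R)),
multiplicative scatter correction against a training-set mean reference,
then a per-spectrum running median.  The MSC reference is learned on
training data and frozen when applied to new spectra, so no test-set
information leaks into the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .dataset import ABSORBANCE, REFLECTANCE, SpectralDataset

__all__ = ["MSCModel", "reflectance_to_absorbance", "msc_fit", "msc_apply",
           "msc_coefficients", "median_smooth", "preprocess",
           "save_msc_reference", "load_msc_reference"]

_B_TOL = 1e-12


def reflectance_to_absorbance(dataset: SpectralDataset) -> SpectralDataset:
    """Convert reflectance spectra to absorbance, A = log10(1/R)."""
    if dataset.domain_tag != REFLECTANCE:
        raise ValueError("dataset is not tagged as reflectance")
    if dataset.values.size and np.any(dataset.values <= 0):
        i, j = np.argwhere(dataset.values <= 0)[0]
        raise ValueError(
            f"non-positive reflectance at sample {i}, "
            f"wavelength {dataset.wavelengths[j]:g} nm"
        )
    return replace(dataset, values=-np.log10(dataset.values),
                   domain_tag=ABSORBANCE)


@dataclass
class MSCModel:
    """Multiplicative scatter correction model.

    ``reference`` is the mean training spectrum.  ``offsets``/``gains``
    hold the per-spectrum least-squares coefficients (a, b) of the
    training set: each spectrum x is regressed as x ≈ a + b·reference and
    corrected to (x − a) / b.
    """

    reference: np.ndarray
    offsets: np.ndarray | None = None
    gains: np.ndarray | None = None


def _fit_coefficients(values: np.ndarray, reference: np.ndarray):
    """Per-row OLS of each spectrum on the reference: x ≈ a + b·ref."""
    ref = reference - reference.mean()
    denom = float(ref @ ref)
    if denom < _B_TOL:
        raise ValueError("MSC reference is constant; regression degenerate")
    xc = values - values.mean(axis=1, keepdims=True)
    b = xc @ ref / denom
    a = values.mean(axis=1) - b * reference.mean()
    return a, b


def msc_fit(train: SpectralDataset) -> MSCModel:
    """Fit an MSC model: reference = column mean of the training spectra."""
    if train.n_samples == 0:
        raise ValueError("cannot fit MSC on an empty dataset")
    reference = train.values.mean(axis=0)
    a, b = _fit_coefficients(train.values, reference)
    return MSCModel(reference=reference, offsets=a, gains=b)


def msc_coefficients(model: MSCModel, dataset: SpectralDataset):
    """Return the per-spectrum (a, b) of ``dataset`` against the reference."""
    if dataset.n_wavelengths != model.reference.size:
        raise ValueError(
            f"dataset has {dataset.n_wavelengths} wavelengths but MSC "
            f"reference has {model.reference.size}"
        )
    return _fit_coefficients(dataset.values, model.reference)


def msc_apply(model: MSCModel, dataset: SpectralDataset) -> SpectralDataset:
    """Correct each spectrum to (x − a) / b with the frozen reference."""
    if dataset.n_samples == 0:
        return dataset
    a, b = msc_coefficients(model, dataset)
    if np.any(np.abs(b) < _B_TOL):
        i = int(np.argmax(np.abs(b) < _B_TOL))
        raise ValueError(f"degenerate spectrum {i}: MSC gain |b| < {_B_TOL}")
    corrected = (dataset.values - a[:, None]) / b[:, None]
    return replace(dataset, values=corrected)


def save_msc_reference(model: MSCModel, path, wavelengths=None) -> None:
    """Persist the MSC reference spectrum as a one-row CSV for reuse."""
    import pandas as pd
    cols = ([f"λ{w:g}" for w in wavelengths] if wavelengths is not None
            else [f"c{i}" for i in range(model.reference.size)])
    pd.DataFrame([model.reference], columns=cols).to_csv(path, index=False)


def load_msc_reference(path) -> MSCModel:
    """Load a persisted MSC reference; returns a model ready for apply."""
    import pandas as pd
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] != 1:
        raise ValueError(f"{path}: expected exactly one reference row")
    return MSCModel(reference=df.to_numpy(dtype=float)[0])


def median_smooth(dataset: SpectralDataset, window: int = 5) -> SpectralDataset:
    """Per-spectrum running median with replicate (edge-value) padding."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > dataset.n_wavelengths:
        raise ValueError("window exceeds spectrum length")
    if window == 1 or dataset.n_samples == 0:
        return dataset
    smoothed = median_filter(dataset.values, size=(1, window), mode="nearest")
    return replace(dataset, values=smoothed)


def preprocess(dataset: SpectralDataset, window: int = 5,
               msc_model: MSCModel | None = None):
    """Full chain: absorbance → MSC → median smooth.

    When ``msc_model`` is None a model is fitted on ``dataset`` itself;
    pass a frozen model to apply a training-set reference to new data.
    Returns ``(preprocessed dataset, msc model)``.
    """
    absorb = reflectance_to_absorbance(dataset)
    if msc_model is None:
        msc_model = msc_fit(absorb)
    corrected = msc_apply(msc_model, absorb)
    return median_smooth(corrected, window=window), msc_model
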