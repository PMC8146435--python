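"""Labelled spectral datasets and their delimited-text serialisation.

The pipeline's currency is a :class:`SpectralDataset`: a samples-by-wavelengths
matrix of reflectance (or absorbance) values with one class label per row.
Files are wide CSV: a ``label`` column followed by one column per wavelength,
headers spelled ``λ400, λ402, …`` (a plain numeric header is also accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "ParseError", "read_dataset", "write_dataset"]

REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"


class ParseError(ValueError):
    """A spectral CSV could not be parsed; the message names row/column."""


@dataclass
class SpectralDataset:
    """Per-sample spectra with class labels.

    Parameters
    ----------
    wavelengths : array of float, nm, strictly increasing
    values : (n_samples, n_wavelengths) float array
    labels : (n_samples,) array of class-name strings
    domain_tag : ``"reflectance"`` or ``"absorbance"``
    """

    wavelengths: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    domain_tag: str = REFLECTANCE

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.size == 0:
            self.values = self.values.reshape(0, self.wavelengths.size)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.labels.size != self.values.shape[0]:
            raise ValueError(
                f"{self.labels.size} labels for {self.values.shape[0]} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")
        if self.domain_tag not in (REFLECTANCE, ABSORBANCE):
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")

    # -- conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct labels in sorted order (D0 < D1 < … lexically)."""
        return tuple(sorted({str(l) for l in self.labels}))

    def select_bands(self, indices) -> "SpectralDataset":
        """Restrict the dataset to the given wavelength indices."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self, wavelengths=self.wavelengths[idx], values=self.values[:, idx]
        )

    def take(self, rows) -> "SpectralDataset":
        rows = np.asarray(rows, dtype=int)
        return replace(self, values=self.values[rows], labels=self.labels[rows])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [_wavelength_header(w) for w in self.wavelengths]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", self.labels)
        return df

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            self.domain_tag == other.domain_tag
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.values, other.values)
            and list(self.labels) == list(other.labels)
        )


def _wavelength_header(w: float) -> str:
    return f"λ{w:g}"


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Write a dataset as wide CSV with a ``label`` column and λ-headers."""
    path = Path(path)
    df = dataset.to_dataframe()
    # shortest round-trip reprs; paired with float_precision="round_trip"
    # on read so that read(write(d)) is exact
    df.to_csv(path, index=False)


def read_dataset(path, domain_tag: str = REFLECTANCE) -> SpectralDataset:
    """Read a wide spectral CSV written by :func:`write_dataset`.

    Raises
    ------
    ParseError
        On a malformed header, a missing or non-numeric cell (the message
        names the offending row and column), or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if df.columns.size == 0 or df.columns[0] != "label":
        raise ParseError(f"{path}: first header field must be 'label'")
    wavelengths = []
    for col in df.columns[1:]:
        text = str(col)
        if text.startswith("λ"):
            text = text[1:]
        try:
            wavelengths.append(float(text))
        except ValueError as exc:
            raise ParseError(
                f"{path}: header column {col!r} is not a wavelength"
            ) from exc
    values = df.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: missing or non-numeric cell at data row {r + 1}, "
            f"column {values.columns[c]!r}"
        )
    labels = df["label"].astype(str).to_numpy(dtype=object)
    if df.shape[0] and pd.isna(df["label"]).any():
        r = int(np.argwhere(pd.isna(df['label']).to_numpy())[0])
        raise ParseError(f"{path}: missing label at data row {r + 1}")
    return SpectralDataset(
        wavelengths=np.asarray(wavelengths, dtype=float),
        values=numeric.to_numpy(dtype=float).reshape(df.shape[0], len(wavelengths)),
        labels=labels,
        domain_tag=domain_tag,
    )
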