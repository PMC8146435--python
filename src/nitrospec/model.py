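"""Model/Results front end for the whole analysis.

:class:`NitrogenClassificationModel` is built from a labelled spectral
dataset (or a wide DataFrame) plus the analysis configuration; ``fit()``
runs preprocessing, optional effective-wavelength selection and the
repeated-split five-classifier + majority-vote evaluation, and returns a
:class:`NitrogenClassificationResults` carrying the selection, pooled
confusion matrices, per-iteration CCR/AUC series and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import default_classifiers
from .dataset import SpectralDataset
from .evaluation import (EvaluationReport, SplitScheme, per_class_metrics,
                         repeated_evaluation)
from .metaheuristics import BBOParams, HSParams, ICAParams
from .preprocessing import preprocess
from .selection import SelectionResult, select_wavelengths

__all__ = ["NitrogenClassificationModel", "NitrogenClassificationResults"]


class NitrogenClassificationModel:
    """Nitrogen-treatment classification from leaf spectra.

    Parameters
    ----------
    dataset : SpectralDataset
        Labelled reflectance spectra (or absorbance with ``preprocess=False``).
    preprocess : bool
        Apply absorbance → MSC → median smoothing first (default True).
    smoothing_window : int
        Median-filter width in bands.
    bands : "auto" | sequence of int | None
        "auto" runs BBO wavelength selection, a sequence fixes the band
        indices, None uses the entire grid.
    selection_k : int
        Subset size for "auto" selection.
    """

    def __init__(self, dataset: SpectralDataset, *, preprocess: bool = True,
                 smoothing_window: int = 5, bands="auto",
                 selection_k: int = 3,
                 selection_params: BBOParams | None = None,
                 ica_params: ICAParams | None = None,
                 hs_params: HSParams | None = None,
                 n_rbf_centers: int = 4,
                 refine_epochs: int = 200,
                 scheme: SplitScheme | None = None,
                 seed: int = 0):
        self.dataset = dataset
        self.do_preprocess = preprocess
        self.smoothing_window = smoothing_window
        self.bands = bands
        self.selection_k = selection_k
        self.selection_params = selection_params
        self.ica_params = ica_params
        self.hs_params = hs_params
        self.n_rbf_centers = n_rbf_centers
        self.refine_epochs = refine_epochs
        self.scheme = scheme or SplitScheme(iterations=20, seed=seed)
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        """Build from a wide frame: a ``label`` column + one column per nm."""
        wl = []
        for col in df.columns:
            if col == "label":
                continue
            text = str(col)
            wl.append(float(text[1:] if text.startswith("λ") else text))
        ds = SpectralDataset(
            wavelengths=np.asarray(wl, dtype=float),
            values=df.drop(columns=["label"]).to_numpy(dtype=float),
            labels=df["label"].astype(str).to_numpy(dtype=object))
        return cls(ds, **kwargs)

    def _classifier_factory(self, seed: int):
        return default_classifiers(
            seed=seed, ica_params=self.ica_params, hs_params=self.hs_params,
            n_rbf_centers=self.n_rbf_centers,
            refine_epochs=self.refine_epochs)

    def fit(self) -> "NitrogenClassificationResults":
        data = self.dataset
        msc_model = None
        if self.do_preprocess:
            data, msc_model = preprocess(data, window=self.smoothing_window)
        selection = None
        if isinstance(self.bands, str) and self.bands == "auto":
            selection = select_wavelengths(
                data, k=self.selection_k, params=self.selection_params,
                split_seed=self.seed)
            data = data.select_bands(selection.indices)
        elif self.bands is not None:
            data = data.select_bands(list(self.bands))
        report = repeated_evaluation(data, self._classifier_factory,
                                     self.scheme)
        return NitrogenClassificationResults(self, data, selection, report,
                                             msc_model)


class NitrogenClassificationResults:
    """Fitted-analysis container with summary and metric accessors."""

    def __init__(self, model, data, selection: SelectionResult | None,
                 report: EvaluationReport, msc_model=None):
        self.model = model
        self.data = data
        self.selection = selection
        self.report = report
        self.msc_model = msc_model

    @property
    def classes(self):
        return self.report.classes

    @property
    def confusion_matrices(self):
        return self.report.pooled

    def pooled_ccr(self) -> pd.Series:
        return pd.Series(self.report.pooled_ccr())

    def metrics(self, classifier: str = "MV",
                convention: str = "study") -> pd.DataFrame:
        return per_class_metrics(self.report.pooled[classifier],
                                 convention=convention)

    def mean_auc(self) -> pd.DataFrame:
        return self.report.mean_auc()

    def summary(self) -> str:
        lines = ["Nitrogen-treatment classification from leaf spectra",
                 "=" * 52]
        if self.selection is not None:
            wl = ", ".join(f"{w:g} nm" for w in self.selection.wavelengths)
            lines.append(f"Selected wavelengths (ANN-BBO): {wl}")
        else:
            lines.append(f"Bands used: {self.data.n_wavelengths}")
        lines.append(f"Iterations: {self.report.iterations}   "
                     f"classes: {', '.join(self.classes)}")
        lines.append("")
        lines.append("Pooled correct classification rate (%):")
        for name, value in self.report.pooled_ccr().items():
            lines.append(f"  {name:8s} {value:6.2f}")
        lines.append("")
        lines.append("Majority-vote per-class metrics (%):")
        lines.append(self.metrics("MV").round(2).to_string())
        lines.append("")
        lines.append("Mean one-vs-rest AUC over iterations:")
        lines.append(self.mean_auc().round(4).to_string())
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<NitrogenClassificationResults: {self.report.iterations} "
                f"iterations, {len(self.classes)} classes>")
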