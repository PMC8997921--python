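"""Interpretive diagnostics for spectroscopy calibrations.

Covers the analyses used to judge what a calibration actually measures:
explained-variance curves of reference and spectral blocks, the FA
correlation structure, normalized regression-coefficient profiles,
prediction-covariance inflation, and the absolute-vs-proportional
"cage of covariance" analysis, in which models trained on absolute contents
(% of sample) are unmasked as fat predictors while proportional models
(% of total FA) track the individual fatty acid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import CalibrationModel, cross_validate, r2_score, select_components
from .containers import CompositionTable


def explained_variance_curves(blocks: dict[str, np.ndarray],
                              n_components: int = 13) -> pd.DataFrame:
    """Cumulative percent variance of the leading principal components.

    Each block is column mean-centered and decomposed by SVD; curves beyond
    the block's rank are padded at 100%.  Returns a DataFrame indexed by
    component number (1..n_components) with one column per block.
    """
    curves = {}
    for name, x in blocks.items():
        x = np.asarray(x, dtype=float)
        xc = x - x.mean(axis=0)
        s = np.linalg.svd(xc, compute_uv=False)
        var = s**2
        total = var.sum()
        if total == 0:
            raise ValueError(f"block {name!r} has zero variance")
        cum = np.cumsum(var) / total * 100.0
        if len(cum) < n_components:
            cum = np.concatenate([cum, np.full(n_components - len(cum), 100.0)])
        curves[name] = cum[:n_components]
    return pd.DataFrame(curves, index=pd.RangeIndex(1, n_components + 1, name="component"))


def correlation_matrix(table: pd.DataFrame | CompositionTable) -> pd.DataFrame:
    """Pearson correlations between columns, pairwise over complete values.

    Zero-variance columns give NaN entries (flagged with a warning), never a
    silent 0.
    """
    df = table.values if isinstance(table, CompositionTable) else pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need at least 3 samples for correlations")
    constant = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"zero-variance columns give undefined correlations: {constant}",
                      stacklevel=2)
    return df.corr(method="pearson")


def covariance_inflation(pred_table: pd.DataFrame, ref_table: pd.DataFrame,
                         use: str = "correlation") -> float:
    """Mean absolute off-diagonal association of predictions over references.

    With ``use='correlation'`` (default) the statistic is
    mean|off-diag corr(predictions)| / mean|off-diag corr(references)|;
    1.08 means the predictions inter-correlate 8% more strongly than the
    reference values do.  ``use='covariance'`` computes the scale-bearing
    variant.
    """
    pred = pd.DataFrame(pred_table)
    ref = pd.DataFrame(ref_table)
    if list(pred.columns) != list(ref.columns) or len(pred) != len(ref):
        raise ValueError("prediction and reference tables must match in shape/columns")
    if pred.shape[1] < 2:
        raise ValueError("need at least 2 columns for off-diagonal structure")

    def mean_abs_offdiag(df: pd.DataFrame) -> float:
        m = df.corr().to_numpy() if use == "correlation" else np.cov(df.to_numpy().T)
        if np.isnan(m).any():
            raise ValueError("degenerate (zero-variance) column in table")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        return float(np.mean(np.abs(off)))

    denom = mean_abs_offdiag(ref)
    if denom == 0:
        raise ValueError("reference table has no off-diagonal association")
    return mean_abs_offdiag(pred) / denom


def coefficient_profile(model: CalibrationModel, axis: np.ndarray,
                        a: int | None = None) -> pd.Series:
    """Regression-coefficient vector at the chosen component count, unit-normalized.

    Normalization (Euclidean) makes profiles of different targets directly
    comparable; the index carries the spectral axis for band lookup.
    """
    a = a or model.chosen_a or model.a_max
    coef = model.coefficients[:, a - 1]
    norm = np.linalg.norm(coef)
    if norm == 0:
        raise ValueError("zero coefficient vector")
    axis = np.asarray(axis, dtype=float)
    if axis.shape != coef.shape:
        raise ValueError("axis length must match coefficient length")
    return pd.Series(coef / norm, index=pd.Index(axis, name="axis"))


def cage_analysis(X: np.ndarray, comps: CompositionTable, a_max: int = 20,
                  k: int = 7, rule: str = "min",
                  fa_names: list[str] | None = None) -> pd.DataFrame:
    """Absolute-vs-proportional calibration comparison per fatty acid.

    For each FA four cross-validated quantities are computed:

    * ``r2_absolute`` — CV R² of the model trained on absolute contents
      (% of sample, i.e. V·fat/100);
    * ``r2_proportional`` — CV R² of the model trained on proportional
      contents (% of total FA);
    * ``r2_abs_div_fat`` — R² of absolute-model predictions ÷ fat against
      the proportional reference;
    * ``r2_prop_times_fat`` — R² of proportional-model predictions × fat
      against the absolute reference;

    plus the correlation of each model's predictions with fat content.  A
    high ``corr_fat_absolute`` with ``corr_fat_proportional`` near zero is
    the signature of absolute-content models predicting fat rather than the
    individual FA.
    """
    X = np.asarray(X, dtype=float)
    fat = comps.fat.to_numpy()
    fat_varies = float(np.std(fat)) > 0

    def corr_with_fat(pred: np.ndarray) -> float:
        return float(np.corrcoef(pred, fat)[0, 1]) if fat_varies else float("nan")

    rows = []
    for name in (fa_names or comps.fa_names):
        v = comps.column(name)
        v_abs = v * fat / 100.0

        cv_abs = cross_validate(X, v_abs, a_max, k)
        a_abs = select_components(cv_abs, rule)
        pred_abs = cv_abs.predictions[:, a_abs - 1]

        cv_prop = cross_validate(X, v, a_max, k)
        a_prop = select_components(cv_prop, rule)
        pred_prop = cv_prop.predictions[:, a_prop - 1]

        rows.append({
            "fa": name,
            "a_absolute": a_abs,
            "a_proportional": a_prop,
            "r2_absolute": float(cv_abs.r2cv[a_abs - 1]),
            "r2_proportional": float(cv_prop.r2cv[a_prop - 1]),
            "r2_abs_div_fat": r2_score(v, pred_abs / fat * 100.0),
            "r2_prop_times_fat": r2_score(v_abs, pred_prop * fat / 100.0),
            "corr_fat_absolute": corr_with_fat(pred_abs),
            "corr_fat_proportional": corr_with_fat(pred_prop),
        })
    return pd.DataFrame(rows).set_index("fa")


@dataclass
class DiagnosticsReport:
    """Bundle of the interpretive analyses for one dataset/run."""

    explained_variance: pd.DataFrame | None = None
    reference_correlation: pd.DataFrame | None = None
    predicted_correlation: pd.DataFrame | None = None
    covariance_inflation_ratio: float | None = None
    covariance_inflation_cov: float | None = None
    cage: pd.DataFrame | None = None
    coefficient_profiles: dict[str, pd.Series] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def df(x):
            return None if x is None else json.loads(x.to_json(orient="split"))
        out = {
            "explained_variance": df(self.explained_variance),
            "reference_correlation": df(self.reference_correlation),
            "predicted_correlation": df(self.predicted_correlation),
            "covariance_inflation_ratio": self.covariance_inflation_ratio,
            "covariance_inflation_cov": self.covariance_inflation_cov,
            "cage": df(self.cage),
            "coefficient_profiles": {k: v.tolist() for k, v in self.coefficient_profiles.items()},
        }
        Path(path).write_text(json.dumps(out, indent=2))
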