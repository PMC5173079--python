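"""Linear soft-margin SVM supplying per-sample decision values.

The classifier behind every panel evaluation is the standard C-soft-margin
linear SVM; a sample's decision value is ``f(x) = w . x + w0`` and its
predicted class is the positive cohort iff ``f(x) > 0``.  The positive
cohort is, by convention, the disease listed first in a comparison
("PC vs CP" scores PC positive), which fixes the sign of the decision
values exported for box plots.

Fits go through libsvm's low-level binding (the solver behind
``sklearn.svm.SVC``) because bootstrap-wrapped feature selection performs
on the order of 10^5 fits per run and the estimator-level API spends most
of its time re-validating inputs.  The orientation convention of the raw
solver output (``w = -(sv_coef . SV)``, ``w0 = -intercept``, positive
decision for the +1 label) is pinned by a regression test against ``SVC``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import _libsvm as _libsvm

from .preprocess import ExpressionMatrix

__all__ = ["LinearModel", "train_svm", "decision_values", "save_model", "load_model"]

_libsvm.set_verbosity_wrap(0)

DEFAULT_COST = 1.0
#: libsvm's own stopping tolerance; tight enough for the decision values and
#: metrics here, and avoids the solver's pathological cycling on degenerate
#: 1-D subproblems at much smaller tolerances.  Pass a smaller ``tol``
#: explicitly where the exact (w, w0) matter.
DEFAULT_TOL = 1e-3
#: hard cap on solver iterations as a safety net against cycling; never hit
#: at the default tolerance on the problem sizes this package handles.
MAX_ITER = 1_000_000


@dataclass
class LinearModel:
    """A trained linear SVM over a miRNA panel: f(x) = w . x + w0."""

    panel: tuple[str, ...]
    w: np.ndarray
    w0: float
    C: float
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.panel),):
            raise ValueError("weight vector length must equal panel size")


def fit_linear(
    X: np.ndarray, y: np.ndarray, C: float = DEFAULT_COST, tol: float = DEFAULT_TOL
) -> tuple[np.ndarray, float]:
    """Solve the C-soft-margin linear SVM on (X, y in {-1,+1}); return (w, w0)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    out = _libsvm.fit(
        X, y, svm_type=0, kernel="linear", C=float(C), tol=float(tol),
        max_iter=MAX_ITER,
    )
    sv, sv_coef, intercept = out[1], out[3], out[4]
    w = -(sv_coef @ sv).ravel()
    return w, float(-intercept[0])


def train_svm(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    positive: str,
    negative: str,
    C: float = DEFAULT_COST,
    tol: float = DEFAULT_TOL,
) -> LinearModel:
    """Train a linear SVM on the samples labelled ``positive``/``negative``.

    ``expr`` must already be restricted to the panel's miRNA columns and be
    on a common (standardized) scale.  Deterministic for identical input.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    labels = labels.loc[values.index]
    mask_pos = (labels == positive).to_numpy()
    mask_neg = (labels == negative).to_numpy()
    if not mask_pos.any() or not mask_neg.any():
        missing = positive if not mask_pos.any() else negative
        raise ValueError(f"class {missing!r} has no samples in the training set")
    keep = mask_pos | mask_neg
    X = values.to_numpy(dtype=float)[keep]
    y = np.where(mask_pos[keep], 1.0, -1.0)
    w, w0 = fit_linear(X, y, C=C, tol=tol)
    return LinearModel(
        panel=tuple(values.columns),
        w=w,
        w0=w0,
        C=C,
        positive_label=positive,
        negative_label=negative,
    )


def decision_values(
    model: LinearModel, expr: ExpressionMatrix | pd.DataFrame
) -> pd.Series:
    """Per-sample decision values f(x) = w . x + w0 for the model's panel."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [m for m in model.panel if m not in values.columns]
    if missing:
        raise ValueError(f"expression matrix lacks panel miRNAs: {missing}")
    X = values[list(model.panel)].to_numpy(dtype=float)
    return pd.Series(X @ model.w + model.w0, index=values.index, name="decision")


def save_model(model: LinearModel, path: str | Path) -> Path:
    """Serialize a model as flat ``key = value`` text."""
    path = Path(path)
    lines = [
        f"panel = {','.join(model.panel)}",
        f"w = {','.join(repr(float(v)) for v in model.w)}",
        f"w0 = {float(model.w0)!r}",
        f"C = {float(model.C)!r}",
        f"positive_label = {model.positive_label}",
        f"negative_label = {model.negative_label}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def load_model(path: str | Path) -> LinearModel:
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    return LinearModel(
        panel=tuple(fields["panel"].split(",")),
        w=np.array([float(v) for v in fields["w"].split(",")]),
        w0=float(fields["w0"]),
        C=float(fields["C"]),
        positive_label=fields["positive_label"],
        negative_label=fields["negative_label"],
    )
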