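"""Balanced bootstrap hold-out validation of a fixed miRNA panel.

Each replicate (i) downsamples both cohorts to the size of the smaller one
(balancing, without replacement within class), (ii) randomly holds out a
fixed number of samples for testing, (iii) trains the linear SVM on the
remainder, and (iv) scores the hold-out: accuracy, sensitivity,
specificity, and rank AUC of the decision values.  Metrics are summarized
as (mean, SE) across replicates, where "SE" is the standard deviation of
the metric over replicates — the bootstrap estimate of its sampling SD,
the quantity the Z comparison of AUCs consumes.

Hold-out draws are stratified only in the weak sense that a draw whose
test (or training) side lacks a class is redrawn, up to 100 times; a
replicate whose hold-out still lacks a class contributes accuracy but not
the class-conditional metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .rocstats import auc as rank_auc
from .svm import DEFAULT_COST, DEFAULT_TOL, fit_linear

__all__ = [
    "MetricSummary",
    "PerfSummary",
    "balanced_sample",
    "bootstrap_validate",
    "bootstrap_validate_marker",
]


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    se: float
    n: int  # contributing replicates


@dataclass(eq=False)
class PerfSummary:
    """One performance-table row: accuracy/sensitivity/specificity/AUC with SEs."""

    accuracy: MetricSummary
    sensitivity: MetricSummary
    specificity: MetricSummary
    auc: MetricSummary
    n_reps: int
    holdout: int
    comparison: tuple[str, str]
    panel: tuple[str, ...]
    n_retries: int = 0
    replicates: pd.DataFrame | None = field(default=None, repr=False)
    decisions: pd.DataFrame | None = field(default=None, repr=False)

    def as_row(self) -> dict:
        row: dict = {
            "comparison": f"{self.comparison[0]} vs {self.comparison[1]}",
            "panel": "+".join(self.panel),
        }
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            m: MetricSummary = getattr(self, name)
            row[name] = m.mean
            row[f"{name}_se"] = m.se
        row["n_reps"] = self.n_reps
        row["holdout"] = self.holdout
        return row


def balanced_sample(labels: pd.Series, seed) -> pd.Index:
    """Equal-size class subsample: 2*min(n_pos, n_neg) ids, drawn without
    replacement within each class.  ``labels`` must hold exactly two classes."""
    rng = np.random.default_rng(seed)
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"balanced_sample needs exactly 2 classes, got {list(classes)}")
    groups = [labels.index[labels == c].to_numpy() for c in classes]
    if min(len(g) for g in groups) == 0:
        raise ValueError("both classes must be nonempty")
    m = min(len(g) for g in groups)
    picks = [rng.choice(g, size=m, replace=False) for g in groups]
    return pd.Index(np.concatenate(picks))


def _summarize(values: np.ndarray) -> MetricSummary:
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        return MetricSummary(float("nan"), float("nan"), 0)
    mean = float(values[ok].mean())
    se = float(values[ok].std(ddof=1)) if n > 1 else 0.0
    return MetricSummary(mean, se, n)


def _bootstrap(
    ids: np.ndarray,
    y: np.ndarray,
    decide: Callable[[np.ndarray, np.ndarray], np.ndarray],
    holdout: int,
    n_reps: int,
    seed,
    comparison: tuple[str, str],
    panel: tuple[str, ...],
    collect_decisions: bool,
) -> PerfSummary:
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y > 0)
    neg_idx = np.flatnonzero(y < 0)
    m = min(len(pos_idx), len(neg_idx))
    if 2 * m < holdout + 4:
        raise ValueError(
            f"too few samples: balancing gives {2 * m}, need at least {holdout + 4} "
            f"(holdout {holdout} + 4 training samples)"
        )
    acc = np.full(n_reps, np.nan)
    sens = np.full(n_reps, np.nan)
    spec = np.full(n_reps, np.nan)
    aucs = np.full(n_reps, np.nan)
    retries = 0
    dec_parts: list[pd.DataFrame] = []

    for r in range(n_reps):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=m, replace=False),
                rng.choice(neg_idx, size=m, replace=False),
            ]
        )
        yb = y[take]
        train = test = None
        for attempt in range(100):
            perm = rng.permutation(2 * m)
            tr, te = take[perm[holdout:]], take[perm[:holdout]]
            ytr, yte = y[tr], y[te]
            if (ytr > 0).any() and (ytr < 0).any():
                train, test = tr, te
                if (yte > 0).any() and (yte < 0).any():
                    break
            retries += 1
        if train is None:  # pragma: no cover - only possible at extreme holdout
            raise RuntimeError("could not draw a training split containing both classes")
        d = decide(train, test)
        yte = y[test]
        pred_pos = d > 0
        is_pos = yte > 0
        acc[r] = float((pred_pos == is_pos).mean())
        if is_pos.any():
            sens[r] = float(pred_pos[is_pos].mean())
        if (~is_pos).any():
            spec[r] = float((~pred_pos[~is_pos]).mean())
        if is_pos.any() and (~is_pos).any():
            aucs[r] = rank_auc(d, is_pos)
        if collect_decisions:
            dec_parts.append(
                pd.DataFrame(
                    {
                        "replicate": r,
                        "sample_id": ids[test],
                        "cohort": np.where(is_pos, comparison[0], comparison[1]),
                        "decision": d,
                    }
                )
            )

    replicates = pd.DataFrame(
        {"accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": aucs}
    )
    replicates.index.name = "replicate"
    return PerfSummary(
        accuracy=_summarize(acc),
        sensitivity=_summarize(sens),
        specificity=_summarize(spec),
        auc=_summarize(aucs),
        n_reps=n_reps,
        holdout=holdout,
        comparison=comparison,
        panel=panel,
        n_retries=retries,
        replicates=replicates,
        decisions=pd.concat(dec_parts, ignore_index=True) if dec_parts else None,
    )


def _prepare(values: pd.DataFrame, labels: pd.Series, positive: str, negative: str):
    labels = labels.loc[labels.index.intersection(values.index)]
    keep = labels[labels.isin([positive, negative])].index
    if len(keep) == 0:
        raise ValueError(f"no samples labelled {positive!r} or {negative!r}")
    values = values.loc[keep]
    y = np.where((labels.loc[keep] == positive).to_numpy(), 1.0, -1.0)
    if (y > 0).sum() == 0 or (y < 0).sum() == 0:
        missing = positive if (y > 0).sum() == 0 else negative
        raise ValueError(f"class {missing!r} is empty")
    return values, keep.to_numpy(), y


def bootstrap_validate(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    panel,
    positive: str,
    negative: str,
    holdout: int = 10,
    n_reps: int = 1000,
    C: float = DEFAULT_COST,
    seed=0,
    tol: float = DEFAULT_TOL,
    collect_decisions: bool = False,
) -> PerfSummary:
    """Balanced bootstrap hold-out validation of an SVM on ``panel``.

    Per replicate: balance classes, hold out ``holdout`` samples, train the
    C-soft-margin linear SVM on the rest, score the hold-out.  Fixed seed
    gives an identical summary.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    panel = tuple(panel)
    missing = [p for p in panel if p not in values.columns]
    if missing:
        raise ValueError(f"expression matrix lacks panel miRNAs: {missing}")
    values, ids, y = _prepare(values[list(panel)], labels, positive, negative)
    X = np.ascontiguousarray(values.to_numpy(dtype=float))

    def decide(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        w, w0 = fit_linear(X[train], y[train], C=C, tol=tol)
        return X[test] @ w + w0

    return _bootstrap(
        ids, y, decide, holdout, n_reps, seed, (positive, negative), panel,
        collect_decisions,
    )


def bootstrap_validate_marker(
    values: pd.Series,
    labels: pd.Series,
    positive: str,
    negative: str,
    holdout: int = 10,
    n_reps: int = 1000,
    threshold: float = 37.0,
    seed=0,
    collect_decisions: bool = False,
) -> PerfSummary:
    """Balanced bootstrap evaluation of a raw scalar marker (e.g. CA 19-9).

    The marker value itself is the decision score (no training step); the
    classification threshold (default: the conventional 37 U/mL CA 19-9
    cutoff) only affects accuracy/sensitivity/specificity, not the AUC.
    """
    frame = values.to_frame(name=values.name or "marker")
    frame = frame[np.isfinite(frame.iloc[:, 0])]
    vals, ids, y = _prepare(frame, labels, positive, negative)
    x = vals.to_numpy(dtype=float).ravel()

    def decide(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        return x[test] - threshold

    return _bootstrap(
        ids, y, decide, holdout, n_reps, seed, (positive, negative),
        (str(frame.columns[0]),), collect_decisions,
    )
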