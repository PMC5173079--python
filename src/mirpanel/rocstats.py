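"""ROC construction, rank AUC, and the normal Z comparison of two AUCs.

The AUC is the Mann-Whitney statistic: the probability that a randomly
chosen positive sample's decision value exceeds a randomly chosen negative
one's, ties counting one half — identical to the trapezoidal area under
the empirical ROC curve.

Two AUCs with bootstrap standard errors SE1, SE2 are compared with

    Z = (AUC1 - AUC2) / sqrt(SE1^2 + SE2^2),    P = 1 - Phi(|Z|),

the independent-SE normal test; Z is reported signed (negative when the
panel trails the reference marker) while the one-sided P uses |Z|.  This
is deliberately not DeLong's paired covariance test: the SEs here come
from the balanced bootstrap, and the comparison treats them as the AUCs'
sampling standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AucComparison", "auc", "roc_points", "compare_auc"]


@dataclass(frozen=True)
class AucComparison:
    """One AUC-vs-AUC comparison row: (AUC1, SE1) vs (AUC2, SE2) -> (z, p)."""

    auc1: float
    se1: float
    auc2: float
    se2: float
    z: float
    p: float
    label: str = ""

    def rounded(self) -> dict:
        """Report-precision view: AUC/SE at 3 dp, z at 2 dp, p at 1 dp."""
        return {
            "label": self.label,
            "auc1": round(self.auc1, 3),
            "se1": round(self.se1, 3),
            "auc2": round(self.auc2, 3),
            "se2": round(self.se2, 3),
            "z": round(self.z, 2),
            "p": round(self.p, 1),
        }


def _split(decision, labels) -> tuple[np.ndarray, np.ndarray]:
    decision = np.asarray(decision, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if decision.shape != labels.shape:
        raise ValueError("decision and labels must have equal length")
    pos, neg = decision[labels], decision[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both classes present")
    return pos, neg


def auc(decision, labels) -> float:
    """Mann-Whitney rank AUC of ``decision`` for boolean ``labels`` (True=positive)."""
    pos, neg = _split(decision, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_points(decision, labels) -> np.ndarray:
    """ROC staircase, one threshold per unique decision value.

    Returns an array of (FPR, TPR) rows running from (0, 0) to (1, 1);
    its trapezoidal area equals :func:`auc` (ties produce diagonal
    segments, as the rank AUC requires).
    """
    pos, neg = _split(decision, labels)
    decision = np.asarray(decision, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-decision, kind="stable")
    sorted_labels = labels[order]
    sorted_dec = decision[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # collapse ties: keep the last point of each run of equal decisions
    last_of_run = np.r_[sorted_dec[1:] != sorted_dec[:-1], True]
    tpr = np.r_[0.0, tp[last_of_run] / len(pos)]
    fpr = np.r_[0.0, fp[last_of_run] / len(neg)]
    return np.column_stack([fpr, tpr])


def compare_auc(
    auc1: float, se1: float, auc2: float, se2: float, label: str = ""
) -> AucComparison:
    """Normal Z comparison of two AUCs with independent bootstrap SEs."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    denom = float(np.hypot(se1, se2))
    if denom == 0.0:
        z = 0.0 if auc1 == auc2 else float(np.sign(auc1 - auc2) * np.inf)
    else:
        z = (auc1 - auc2) / denom
    p = float(stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return AucComparison(
        auc1=float(auc1), se1=float(se1), auc2=float(auc2), se2=float(se2),
        z=float(z), p=p, label=label,
    )
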