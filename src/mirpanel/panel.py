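"""SVM-wrapper sequential forward feature selection of miRNA panels.

Starting from the screened candidate list, the selector greedily adds the
marker whose addition maximizes the classifier's resampled performance
(balanced bootstrap with a small hold-out, accuracy by default), stopping
at the target panel size.  Because selection is greedy, the 3-marker panel
is by construction the length-3 prefix of the 6-marker panel.

All candidates within a step are evaluated under the same derived seed
(common random numbers), so candidate scores are directly comparable and
the selected prefix does not depend on the target size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_validate
from .preprocess import ExpressionMatrix
from .screen import t_screen
from .svm import DEFAULT_COST

__all__ = ["Panel", "EvalConfig", "sfs_select", "step_seed"]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class EvalConfig:
    """Inner resampling used to score candidate panels during selection.

    Hold-out 6 mirrors the training-phase evaluation ("six left for
    testing"); 200 replicates keeps selection fast and can be raised to
    1000 for final-quality scores.
    """

    holdout: int = 6
    n_reps: int = 200
    C: float = DEFAULT_COST


@dataclass
class Panel:
    """An ordered selected panel with its score trajectory."""

    members: tuple[str, ...]
    trajectory: tuple[float, ...]
    objective: str
    comparison: tuple[str, str]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("panel members must be unique")
        if len(self.trajectory) != len(self.members):
            raise ValueError("trajectory must have one score per member")

    def prefix(self, size: int) -> "Panel":
        return Panel(
            members=self.members[:size],
            trajectory=self.trajectory[:size],
            objective=self.objective,
            comparison=self.comparison,
            seed=self.seed,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "members": list(self.members),
                    "trajectory": list(self.trajectory),
                    "objective": self.objective,
                    "comparison": list(self.comparison),
                    "seed": self.seed,
                },
                indent=2,
            )
            + "\n"
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Panel":
        d = json.loads(Path(path).read_text())
        return cls(
            members=tuple(d["members"]),
            trajectory=tuple(d["trajectory"]),
            objective=d["objective"],
            comparison=tuple(d["comparison"]),
            seed=d["seed"],
        )


def step_seed(seed: int, step: int) -> int:
    """Per-step evaluation seed, shared by all candidates of that step."""
    return int((seed * 1_000_003 + 7_919 * step + 1) % (2**31))


def sfs_select(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    candidates,
    max_size: int,
    positive: str,
    negative: str,
    objective: str = "accuracy",
    eval_cfg: EvalConfig | None = None,
    seed: int = 0,
    screen_p: pd.Series | None = None,
) -> Panel:
    """Greedy forward selection of a panel of ``max_size`` miRNAs.

    Parameters
    ----------
    candidates
        Screened miRNA identifiers to choose from (columns of ``expr``).
    objective
        ``'accuracy'`` (default) or ``'auc'`` — the bootstrap-mean metric
        maximized at every greedy step.
    screen_p
        Optional per-candidate univariate P values used as the first
        tie-break (smaller wins); computed internally if omitted.  Final
        tie-break is lexicographic by name, so selection is deterministic.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidates must be unique")
    missing = [c for c in candidates if c not in values.columns]
    if missing:
        raise ValueError(f"candidates not in expression matrix: {missing}")
    if not 1 <= max_size <= len(candidates):
        raise ValueError(
            f"max_size must be in [1, {len(candidates)}], got {max_size}"
        )
    if objective not in ("accuracy", "auc"):
        raise ValueError("objective must be 'accuracy' or 'auc'")
    cfg = eval_cfg or EvalConfig()

    labels = labels.loc[labels.index.intersection(values.index)]
    two = labels[labels.isin([positive, negative])]
    if (two == positive).sum() < 2 or (two == negative).sum() < 2:
        raise ValueError("both classes need at least 2 samples for selection")

    if screen_p is None:
        screen_p = t_screen(
            values[candidates],
            two.index[two == positive],
            two.index[two == negative],
        ).table["p"]

    chosen: list[str] = []
    trajectory: list[float] = []
    remaining = list(candidates)
    for step in range(max_size):
        s = step_seed(seed, step)
        best: tuple | None = None
        for cand in remaining:
            perf = bootstrap_validate(
                values[chosen + [cand]],
                two,
                chosen + [cand],
                positive,
                negative,
                holdout=cfg.holdout,
                n_reps=cfg.n_reps,
                C=cfg.C,
                seed=s,
            )
            score = getattr(perf, objective).mean
            # higher score wins; ties by smaller screening P, then name
            key = (score, -float(screen_p.get(cand, 1.0)), cand)
            if best is None or _better(key, best[0]):
                best = (key, cand, score)
        assert best is not None
        chosen.append(best[1])
        trajectory.append(float(best[2]))
        remaining.remove(best[1])
    return Panel(
        members=tuple(chosen),
        trajectory=tuple(trajectory),
        objective=objective,
        comparison=(positive, negative),
        seed=seed,
    )


def _better(key: tuple, ref: tuple) -> bool:
    score, neg_p, name = key
    ref_score, ref_neg_p, ref_name = ref
    if score > ref_score + _TIE_TOL:
        return True
    if score < ref_score - _TIE_TOL:
        return False
    if abs(neg_p - ref_neg_p) > 0:
        return neg_p > ref_neg_p
    return name < ref_name
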