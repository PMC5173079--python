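"""Ct-to-expression preprocessing: U6 normalization and z-score scaling.

Raw qRT-PCR Ct values are first expressed relative to the U6 reference gene
(``expression = Ct_U6 - Ct_miR``, so larger = more abundant), then each
miRNA is standardized by a z-score whose mean/sd are fit on a designated
sample subset (typically the training phase) and applied unchanged to the
rest — avoiding leakage of validation-phase statistics into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synth import REFERENCE_GENE

__all__ = ["ExpressionMatrix", "NormalizationError", "u6_normalize", "zscore_fit_apply"]


class NormalizationError(ValueError):
    pass


@dataclass(eq=False)
class ExpressionMatrix:
    """Sample x miRNA normalized-expression matrix.

    ``values`` rows are samples, columns miRNAs, on the dimensionless
    delta-Ct scale.  After z-scoring, ``standardized`` is True and
    ``scaling`` records the per-miRNA (mean, sd) pairs used.
    """

    values: pd.DataFrame
    standardized: bool = False
    scaling: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise NormalizationError(
                f"non-finite expression value at sample "
                f"{self.values.index[r]!r}, miRNA {self.values.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.columns

    def restrict(self, samples=None, mirnas=None) -> "ExpressionMatrix":
        """Sub-matrix view restricted to the given samples and/or miRNAs."""
        vals = self.values
        if samples is not None:
            vals = vals.loc[list(samples)]
        if mirnas is not None:
            vals = vals[list(mirnas)]
        return replace(self, values=vals)


def u6_normalize(ct: pd.DataFrame, reference: str = REFERENCE_GENE) -> ExpressionMatrix:
    """Normalize a raw Ct table by its reference-gene column.

    Returns ``expression(s, m) = Ct_ref(s) - Ct_m(s)`` with the reference
    column dropped; the orientation makes larger values mean higher
    abundance (a transcript detected earlier than U6 scores positive).
    """
    if reference not in ct.columns:
        raise NormalizationError(f"reference channel {reference!r} not in table")
    ref = pd.to_numeric(ct[reference], errors="coerce")
    bad = ref.index[~np.isfinite(ref.to_numpy(dtype=float))]
    if len(bad):
        raise NormalizationError(
            f"non-finite {reference} Ct for samples {list(bad[:5])!r}"
        )
    targets = ct.drop(columns=reference).astype(float)
    values = targets.rsub(ref, axis=0)
    return ExpressionMatrix(values=values, standardized=False)


def zscore_fit_apply(
    expr: ExpressionMatrix,
    fit_on,
    apply_to=None,
) -> ExpressionMatrix:
    """Z-score each miRNA: fit mean/sd (ddof=1) on ``fit_on``, apply to ``apply_to``.

    ``apply_to`` defaults to all samples of ``expr``.  The returned matrix
    carries the fitted scaling so validation samples are standardized with
    training-phase statistics only.
    """
    fit_on = list(fit_on)
    if len(fit_on) < 2:
        raise NormalizationError("fit_on needs at least 2 samples to estimate a sd")
    apply_ids = list(apply_to) if apply_to is not None else list(expr.sample_ids)
    fit = expr.values.loc[fit_on]
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    degenerate = sd[(sd <= 0) | ~np.isfinite(sd)]
    if len(degenerate):
        raise NormalizationError(
            f"zero variance over fit samples for miRNA {degenerate.index[0]!r}"
        )
    values = (expr.values.loc[apply_ids] - mean) / sd
    scaling = pd.DataFrame({"mean": mean, "sd": sd})
    scaling.index.name = "mirna"
    return ExpressionMatrix(values=values, standardized=True, scaling=scaling)
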