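"""End-to-end pipeline orchestration and paper-style table outputs.

Mirrors the three-phase biomarker study design: candidate markers are
screened and panels selected on training-phase samples only; panels are
then evaluated by balanced bootstrap on the independent validation-phase
samples, and each panel's AUC is compared against CA 19-9 with the normal
Z test.  Every stage's output is written as delimited text (performance
rows in the accuracy/SE/sensitivity/SE/... layout, the comparison table
with AUC1/SE1/AUC2/SE2/Z/P columns, per-sample decision values for box
plots), and every seed and setting is echoed so a rerun reproduces the
numeric outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synth
from .bootstrap import bootstrap_validate, bootstrap_validate_marker
from .panel import EvalConfig, Panel, sfs_select
from .preprocess import u6_normalize, zscore_fit_apply
from .rocstats import compare_auc
from .screen import t_screen
from .svm import DEFAULT_COST
from .synth import CohortSpec, LabeledCohort, generate_cohort, read_cohort

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger("mirpanel")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; all seeds are recorded in output."""

    out_dir: str | Path = "mirpanel-run"
    # input: either a directory with ct.csv/labels.csv, or a synthetic spec
    input_dir: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    comparisons: tuple[tuple[str, str], ...] = (("PC", "CP"), ("PC", "OPN"), ("CP", "OPN"))
    select_comparison: tuple[str, str] = ("PC", "CP")
    alpha: float = 0.05
    panel_sizes: tuple[int, ...] = (3, 6)
    train_holdout: int = 6
    val_holdout: int = 10
    n_reps: int = 1000
    sfs_reps: int = 200
    svm_cost: float = DEFAULT_COST
    objective: str = "accuracy"
    zscore_scope: str = "train"  # 'train' or 'pooled'
    ca199_threshold: float = 37.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.comparisons = tuple(tuple(c) for c in self.comparisons)
        self.select_comparison = tuple(self.select_comparison)
        self.panel_sizes = tuple(sorted(int(s) for s in self.panel_sizes))
        if self.input_dir is None and self.cohort_spec is None:
            self.cohort_spec = CohortSpec(seed=self.seed)
        if self.zscore_scope not in ("train", "pooled"):
            raise ConfigError("zscore_scope must be 'train' or 'pooled'")
        if any(len(c) != 2 for c in self.comparisons):
            raise ConfigError("each comparison must name exactly two cohorts")
        if self.select_comparison not in self.comparisons:
            raise ConfigError("select_comparison must be one of comparisons")
        if list(self.panel_sizes) != sorted(set(self.panel_sizes)):
            raise ConfigError("panel_sizes must be ascending and unique")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a flat YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    spec_keys = {f.name for f in dataclasses.fields(CohortSpec)}
    cfg_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
    spec_kwargs = {k: v for k, v in raw.items() if k in spec_keys}
    cfg_kwargs = {k: v for k, v in raw.items() if k in cfg_keys}
    unknown = set(raw) - spec_keys - cfg_keys - {"simulate"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "mirna_names" in spec_kwargs:
        spec_kwargs["mirna_names"] = tuple(spec_kwargs["mirna_names"])
    if cfg_kwargs.get("input_dir") is None and (raw.get("simulate", True) or spec_kwargs):
        base_seed = int(cfg_kwargs.get("seed", 0))
        spec_kwargs.setdefault("seed", base_seed)
        cfg_kwargs["cohort_spec"] = CohortSpec(**spec_kwargs)
    return PipelineConfig(**cfg_kwargs)


def _comparison_expression(cohort: LabeledCohort, pos: str, neg: str, scope: str):
    """U6-normalize and z-score the samples of one two-cohort comparison.

    Scaling is fit on training-phase samples (scope='train', default) or on
    all samples of the comparison (scope='pooled') and applied to every
    sample of the two cohorts.
    """
    in_cmp = cohort.labels.index[cohort.labels.isin([pos, neg])]
    expr = u6_normalize(cohort.ct.loc[in_cmp])
    if scope == "train":
        fit_on = [s for s in in_cmp if cohort.phase[s] == "training"]
    else:
        fit_on = list(in_cmp)
    return zscore_fit_apply(expr, fit_on=fit_on, apply_to=list(in_cmp))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate/ingest -> normalize -> screen -> select -> validate -> compare.

    Returns the output directory; see the emitted ``run.log`` for the full
    list of files and settings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loglines: list[str] = []

    def stage(msg: str) -> None:
        log.info(msg)
        loglines.append(msg)

    # --- ingest / simulate -------------------------------------------------
    if config.input_dir is not None:
        cohort = read_cohort(config.input_dir)
        stage(f"ingest: read cohort from {config.input_dir}")
    else:
        cohort = generate_cohort(config.cohort_spec)
        stage(f"simulate: generated cohort (seed {config.cohort_spec.seed})")
        synth.write_cohort(cohort, out / "cohort")

    present = set(cohort.labels.unique())
    for pos, neg in config.comparisons:
        missing = {pos, neg} - present
        if missing:
            raise ConfigError(
                f"comparison {pos} vs {neg} names absent cohort(s) {sorted(missing)}"
            )
    phases = set(cohort.phase.unique())
    if config.zscore_scope == "train" and "training" not in phases:
        raise ConfigError("zscore_scope 'train' requires training-phase samples")

    # --- screen + select on the training phase of the primary comparison ---
    sel_pos, sel_neg = config.select_comparison
    expr_sel = _comparison_expression(cohort, sel_pos, sel_neg, config.zscore_scope)
    train_ids = [
        s for s in expr_sel.sample_ids if cohort.phase[s] == "training"
    ]
    train_labels = cohort.labels.loc[train_ids]
    screen_res = t_screen(
        expr_sel.restrict(samples=train_ids),
        [s for s in train_ids if train_labels[s] == sel_pos],
        [s for s in train_ids if train_labels[s] == sel_neg],
        alpha=config.alpha,
    )
    screen_res.table.to_csv(out / f"screen_{sel_pos}_vs_{sel_neg}.csv")
    stage(
        f"screen: {len(screen_res.selected)}/{len(screen_res.table)} miRNAs pass "
        f"P < {config.alpha} ({sel_pos} vs {sel_neg}, training phase)"
    )

    candidates = screen_res.selected or list(screen_res.table.index)
    if not screen_res.selected:
        stage("screen: no miRNA passed; falling back to all candidates")
    max_size = min(max(config.panel_sizes), len(candidates))
    panel_full = sfs_select(
        expr_sel.restrict(samples=train_ids),
        train_labels,
        candidates,
        max_size=max_size,
        positive=sel_pos,
        negative=sel_neg,
        objective=config.objective,
        eval_cfg=EvalConfig(
            holdout=config.train_holdout, n_reps=config.sfs_reps, C=config.svm_cost
        ),
        seed=config.seed,
        screen_p=screen_res.table["p"],
    )
    panels: dict[int, Panel] = {}
    for size in config.panel_sizes:
        size = min(size, max_size)
        panels[size] = panel_full.prefix(size)
        panels[size].to_json(out / f"panel{size}.json")
    stage(f"select: SFS panel {panel_full.members} trajectory {panel_full.trajectory}")

    # --- validate every comparison x panel, plus CA 19-9 -------------------
    perf_rows: list[dict] = []
    cmp_rows: list[dict] = []
    dec_parts: list[pd.DataFrame] = []
    names = {s: f"Panel {'I' * k}" for k, s in enumerate(sorted(panels), start=1)}
    for pos, neg in config.comparisons:
        expr_cmp = _comparison_expression(cohort, pos, neg, config.zscore_scope)
        val_ids = [s for s in expr_cmp.sample_ids if cohort.phase[s] == "validation"]
        val_labels = cohort.labels.loc[val_ids]
        ca_perf = None
        if cohort.ca199 is not None:
            ca_perf = bootstrap_validate_marker(
                cohort.ca199.loc[val_ids],
                val_labels,
                pos,
                neg,
                holdout=config.val_holdout,
                n_reps=config.n_reps,
                threshold=config.ca199_threshold,
                seed=config.seed + 1,
                collect_decisions=False,
            )
        for size in sorted(panels):
            pan = panels[size]
            phases_to_run = [("validation", val_ids, config.val_holdout)]
            if (pos, neg) == config.select_comparison:
                tr_ids = [
                    s for s in expr_cmp.sample_ids if cohort.phase[s] == "training"
                ]
                phases_to_run.insert(0, ("training", tr_ids, config.train_holdout))
            for phase_name, ids, holdout in phases_to_run:
                perf = bootstrap_validate(
                    expr_cmp.restrict(samples=ids),
                    cohort.labels.loc[ids],
                    pan.members,
                    pos,
                    neg,
                    holdout=holdout,
                    n_reps=config.n_reps,
                    C=config.svm_cost,
                    seed=config.seed,
                    collect_decisions=phase_name == "validation",
                )
                row = perf.as_row()
                row["phase"] = phase_name
                row["id"] = names[size]
                perf_rows.append(row)
                if phase_name == "validation":
                    dec = perf.decisions.copy()
                    dec.insert(0, "comparison", f"{pos} vs {neg}")
                    dec.insert(1, "id", names[size])
                    dec_parts.append(dec)
                    if ca_perf is not None:
                        cmp_rows.append(
                            compare_auc(
                                perf.auc.mean,
                                perf.auc.se,
                                ca_perf.auc.mean,
                                ca_perf.auc.se,
                                label=f"{pos} vs {neg} / {names[size]}",
                            ).rounded()
                        )
        if ca_perf is not None:
            row = ca_perf.as_row()
            row["phase"] = "validation"
            row["id"] = "CA 19-9"
            perf_rows.append(row)
            ca_dec = cohort.ca199.loc[val_ids].rename("decision").reset_index()
            ca_dec.insert(0, "comparison", f"{pos} vs {neg}")
            ca_dec.insert(1, "id", "CA 19-9")
            ca_dec["replicate"] = -1
            ca_dec["cohort"] = val_labels.to_numpy()
            dec_parts.append(ca_dec[["comparison", "id", "replicate", "sample_id", "cohort", "decision"]])
        stage(f"validate: {pos} vs {neg} done ({config.n_reps} replicates)")

    perf_cols = [
        "comparison", "phase", "id",
        "accuracy", "accuracy_se", "sensitivity", "sensitivity_se",
        "specificity", "specificity_se", "auc", "auc_se", "n_reps", "holdout",
        "panel",
    ]
    pd.DataFrame(perf_rows)[perf_cols].to_csv(out / "performance.csv", index=False)
    if cmp_rows:
        pd.DataFrame(cmp_rows).to_csv(out / "comparison.csv", index=False)
    if dec_parts:
        pd.concat(dec_parts, ignore_index=True).to_csv(out / "decisions.csv", index=False)
    stage("compare: wrote performance.csv"
          + (", comparison.csv" if cmp_rows else "")
          + (", decisions.csv" if dec_parts else ""))

    # --- reproducibility record -------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["out_dir"] = str(cfg_dict["out_dir"])
    if cfg_dict.get("input_dir") is not None:
        cfg_dict["input_dir"] = str(cfg_dict["input_dir"])
    if config.cohort_spec is not None:
        cfg_dict["cohort_spec"]["mirna_names"] = list(config.cohort_spec.mirna_names)
    (out / "run_config.yml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    (out / "run.log").write_text("\n".join(loglines) + "\n")
    return out
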