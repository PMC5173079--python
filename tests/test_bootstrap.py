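"""Balanced bootstrap hold-out validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpanel import (
    balanced_sample,
    bootstrap_validate,
    bootstrap_validate_marker,
    generate_cohort,
    u6_normalize,
)

from conftest import two_group_spec


def labels_series(n_pos, n_neg):
    idx = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    return pd.Series(["pos"] * n_pos + ["neg"] * n_neg, index=idx)


def null_expr(n_pos, n_neg, n_mirnas=3, seed=0):
    c = generate_cohort(two_group_spec(n_pos, n_neg, 0.0, n_mirnas=n_mirnas, seed=seed))
    return u6_normalize(c.ct), c.labels


class TestBalancedSample:
    def test_downsamples_majority(self):
        out = balanced_sample(labels_series(30, 20), seed=0)
        lab = labels_series(30, 20).loc[out]
        assert len(out) == 40
        assert (lab == "pos").sum() == 20 and (lab == "neg").sum() == 20
        assert out.is_unique

    def test_balanced_input_is_permutation(self):
        lab = labels_series(20, 20)
        out = balanced_sample(lab, seed=1)
        assert sorted(out) == sorted(lab.index)

    def test_empty_class_errors(self):
        lab = pd.Series(["pos"] * 5, index=[f"p{i}" for i in range(5)])
        with pytest.raises(ValueError):
            balanced_sample(lab, seed=0)

    def test_inclusion_frequency_uniform(self):
        """Each majority-class sample is kept with probability 20/30."""
        lab = labels_series(30, 20)
        counts = pd.Series(0, index=lab.index[:30])
        n_draws = 600
        for seed in range(n_draws):
            picked = balanced_sample(lab, seed=seed)
            counts.loc[[s for s in picked if s.startswith("p")]] += 1
        freq = counts / n_draws
        p = 20 / 30
        bound = 4 * np.sqrt(p * (1 - p) / n_draws)  # ~4 sigma per sample
        assert ((freq - p).abs() < bound).all()


class TestBootstrapValidate:
    def test_perfect_separation_scores_near_one(self):
        c = generate_cohort(two_group_spec(40, 40, 6.0, n_mirnas=2, seed=2))
        e = u6_normalize(c.ct)
        perf = bootstrap_validate(e, c.labels, ["M1"], "A", "B",
                                  holdout=10, n_reps=200, seed=0)
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            m = getattr(perf, name)
            assert m.mean >= 0.99
            assert m.se <= 0.05

    def test_null_data_accuracy_near_half(self):
        """Averaged over independent null cohorts the hold-out accuracy is
        chance.  (A single finite cohort has chance structure of order
        sqrt(k/n) that the SVM legitimately picks up, so the null check
        must average over cohorts, not just over replicates.)"""
        means = []
        for seed in range(5):
            e, lab = null_expr(200, 200, seed=seed)
            perf = bootstrap_validate(e, lab, ["M1", "M2", "M3"], "A", "B",
                                      holdout=10, n_reps=80, seed=seed + 1)
            means.append(perf.accuracy.mean)
        assert np.mean(means) == pytest.approx(0.5, abs=0.04)

    def test_single_marker_auc_matches_closed_form(self):
        """Hold-out AUC of a delta=1.5 marker ~ Phi(1.5/sqrt(2)) = 0.856."""
        c = generate_cohort(two_group_spec(200, 200, 1.5, seed=4))
        e = u6_normalize(c.ct)
        perf = bootstrap_validate(e, c.labels, ["M1"], "A", "B",
                                  holdout=50, n_reps=300, seed=2)
        assert perf.auc.mean == pytest.approx(
            stats.norm.cdf(1.5 / np.sqrt(2)), abs=0.04
        )

    def test_fixed_seed_reproducible(self, pc_cp_expression):
        expr, labels = pc_cp_expression
        kw = dict(holdout=10, n_reps=50, seed=9, collect_decisions=True)
        a = bootstrap_validate(expr, labels, ["miR-486-5p"], "PC", "CP", **kw)
        b = bootstrap_validate(expr, labels, ["miR-486-5p"], "PC", "CP", **kw)
        assert a.accuracy == b.accuracy and a.auc == b.auc
        pd.testing.assert_frame_equal(a.decisions, b.decisions)

    def test_mean_within_replicate_range(self, pc_cp_expression):
        expr, labels = pc_cp_expression
        perf = bootstrap_validate(expr, labels, ["miR-486-5p", "miR-126-3p"],
                                  "PC", "CP", holdout=10, n_reps=100, seed=5)
        acc = perf.replicates["accuracy"]
        assert acc.min() <= perf.accuracy.mean <= acc.max()

    def test_doubling_reps_is_stable(self, pc_cp_expression):
        """Mean under 2n replicates stays within the Monte-Carlo error of n."""
        expr, labels = pc_cp_expression
        kw = dict(holdout=10, C=1.0)
        a = bootstrap_validate(expr, labels, ["miR-486-5p"], "PC", "CP",
                               n_reps=400, seed=6, **kw)
        b = bootstrap_validate(expr, labels, ["miR-486-5p"], "PC", "CP",
                               n_reps=800, seed=7, **kw)
        tol = 4 * a.accuracy.se / np.sqrt(400)
        assert abs(a.accuracy.mean - b.accuracy.mean) < tol

    def test_too_few_samples_states_minimum(self):
        e, lab = null_expr(4, 4, seed=0)
        with pytest.raises(ValueError, match="at least 14"):
            bootstrap_validate(e, lab, ["M1"], "A", "B", holdout=10, n_reps=5)

    def test_unknown_panel_member(self, pc_cp_expression):
        expr, labels = pc_cp_expression
        with pytest.raises(ValueError, match="nope"):
            bootstrap_validate(expr, labels, ["nope"], "PC", "CP")

    def test_decisions_cover_both_cohorts(self, pc_cp_expression):
        expr, labels = pc_cp_expression
        perf = bootstrap_validate(expr, labels, ["miR-486-5p"], "PC", "CP",
                                  holdout=10, n_reps=30, seed=3,
                                  collect_decisions=True)
        dec = perf.decisions
        assert set(dec["cohort"].unique()) == {"PC", "CP"}
        assert len(dec) == 30 * 10
        # PC (positive class) scores higher on average
        assert (dec.loc[dec.cohort == "PC", "decision"].mean()
                > dec.loc[dec.cohort == "CP", "decision"].mean())


class TestMarkerBootstrap:
    def test_ca199_auc_near_design_value(self, default_cohort):
        """CA 19-9 PC-vs-CP AUC was designed to sit near 0.775."""
        c = default_cohort
        perf = bootstrap_validate_marker(c.ca199, c.labels, "PC", "CP",
                                         holdout=10, n_reps=500, seed=0)
        assert perf.auc.mean == pytest.approx(0.775, abs=0.08)

    def test_threshold_only_affects_classification(self, default_cohort):
        c = default_cohort
        lo = bootstrap_validate_marker(c.ca199, c.labels, "PC", "CP",
                                       n_reps=100, threshold=10.0, seed=1)
        hi = bootstrap_validate_marker(c.ca199, c.labels, "PC", "CP",
                                       n_reps=100, threshold=100.0, seed=1)
        assert lo.auc == hi.auc
        assert lo.sensitivity.mean > hi.sensitivity.mean
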