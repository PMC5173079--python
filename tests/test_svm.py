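"""Linear SVM: margin geometry, symmetry, and an independent QP oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mirpanel import decision_values, load_model, save_model, train_svm
from mirpanel.svm import fit_linear


def qp_oracle(X, y, C=1.0):
    """Primal soft-margin SVM by constrained optimization (SLSQP):
    minimize 0.5||w||^2 + C * sum(xi) s.t. y_i (w.x_i + b) >= 1 - xi_i, xi >= 0.

    Built independently of the libsvm path; slow but exact enough on toys.
    """
    n, d = X.shape

    def objective(z):
        w = z[:d]
        return 0.5 * w @ w + C * z[d + 1 :].sum()

    def jac(z):
        g = np.zeros_like(z)
        g[:d] = z[:d]
        g[d + 1 :] = C
        return g

    cons = [
        {
            "type": "ineq",
            "fun": lambda z, i=i: y[i] * (X[i] @ z[:d] + z[d]) - 1 + z[d + 1 + i],
        }
        for i in range(n)
    ] + [{"type": "ineq", "fun": lambda z, i=i: z[d + 1 + i]} for i in range(n)]
    best = None
    for x0_scale in (0.0, 0.5, 1.0):
        z0 = np.full(n + d + 1, x0_scale)
        res = minimize(objective, z0, jac=jac, constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:d], best.x[d]


FOUR_POINT_TOYS = [
    # separable square
    (np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]]),
     np.array([-1.0, -1.0, 1.0, 1.0]), 1.0),
    # overlapping pair forcing slack at small C
    (np.array([[-1.0, 0.0], [0.3, 0.1], [-0.3, -0.2], [1.0, 0.0]]),
     np.array([-1.0, -1.0, 1.0, 1.0]), 1.0),
    # anisotropic, larger C
    (np.array([[-2.0, 0.5], [-0.5, -1.0], [0.6, 0.8], [1.5, -0.4]]),
     np.array([-1.0, -1.0, 1.0, 1.0]), 10.0),
]


class TestFitLinear:
    def test_symmetric_1d_margin_midpoint(self):
        """Two points at +-1: the boundary sits at 0, decision +-1 at the points."""
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        w, w0 = fit_linear(X, y, tol=1e-8)
        assert w0 == pytest.approx(0.0, abs=1e-9)
        assert (X @ w + w0)[1] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("X, y, C", FOUR_POINT_TOYS)
    def test_matches_qp_oracle(self, X, y, C):
        w, w0 = fit_linear(X, y, C=C, tol=1e-10)
        w_ref, b_ref = qp_oracle(X, y, C=C)
        np.testing.assert_allclose(w, w_ref, atol=1e-4)
        assert w0 == pytest.approx(b_ref, abs=1e-4)

    def test_matches_public_svc(self, rng):
        """The low-level libsvm path reproduces sklearn.svm.SVC exactly."""
        from sklearn.svm import SVC

        for _ in range(5):
            X = rng.normal(size=(30, 3))
            y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
            y[:2] = [1.0, -1.0]
            X[y > 0] += 0.8
            w, w0 = fit_linear(X, y, tol=1e-6)
            m = SVC(kernel="linear", C=1.0, tol=1e-6).fit(X, y)
            np.testing.assert_allclose(w, m.coef_[0], atol=1e-9)
            assert w0 == pytest.approx(m.intercept_[0], abs=1e-9)

    def test_label_flip_negates_model(self):
        X = np.array([[-1.2, 0.0], [0.3, 0.1], [-0.3, -0.2], [1.0, 0.4]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        w, w0 = fit_linear(X, y, tol=1e-10)
        wf, w0f = fit_linear(X, -y, tol=1e-10)
        np.testing.assert_allclose(w, -wf, atol=1e-8)
        assert w0 == pytest.approx(-w0f, abs=1e-8)

    def test_hard_margin_limit_on_separable_toy(self):
        X = np.array([[-2.0, 0.0], [-1.5, 1.0], [1.5, -0.5], [2.0, 1.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        w, w0 = fit_linear(X, y, C=1e6, tol=1e-10)
        assert (np.abs(X @ w + w0) >= 1 - 1e-6).all()

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(24, 2))
        y = np.where(rng.random(24) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        X[y > 0] += 1.0
        w, w0 = fit_linear(X, y, tol=1e-12)
        for _ in range(3):
            perm = rng.permutation(24)
            wp, w0p = fit_linear(X[perm], y[perm], tol=1e-12)
            np.testing.assert_allclose(w, wp, atol=1e-9)
            assert w0 == pytest.approx(w0p, abs=1e-9)


class TestTrainAndDecide:
    @pytest.fixture
    def trained(self, pc_cp_expression):
        expr, labels = pc_cp_expression
        panel = ["miR-486-5p", "miR-126-3p", "miR-106b-3p"]
        model = train_svm(expr.restrict(mirnas=panel), labels, "PC", "CP")
        return model, expr, labels

    def test_positive_class_orientation(self, trained):
        """PC (listed first) scores positive: mean decision(PC) > mean decision(CP)."""
        model, expr, labels = trained
        d = decision_values(model, expr)
        assert d[labels == "PC"].mean() > d[labels == "CP"].mean()

    def test_decision_is_explicit_dot_product(self, trained, rng):
        model, expr, _ = trained
        sub = expr.restrict(mirnas=model.panel).values.sample(10, random_state=7)
        d = decision_values(model, sub)
        manual = sub.to_numpy() @ model.w + model.w0
        np.testing.assert_allclose(d.to_numpy(), manual, atol=1e-12)

    def test_decision_arithmetic_by_definition(self):
        from mirpanel import LinearModel

        model = LinearModel(
            panel=("a", "b"), w=np.array([1.0, -1.0]), w0=0.5,
            C=1.0, positive_label="P", negative_label="N",
        )
        x = pd.DataFrame({"a": [2.0, 0.0], "b": [1.0, 0.0]}, index=["s1", "s2"])
        d = decision_values(model, x)
        assert d["s1"] == pytest.approx(1.5)
        assert d["s2"] == pytest.approx(0.5)  # zero vector -> w0

    def test_column_mismatch_lists_missing(self, trained):
        model, expr, _ = trained
        with pytest.raises(ValueError, match="miR-106b-3p"):
            decision_values(model, expr.restrict(mirnas=model.panel[:2]))

    def test_absent_class_errors(self, pc_cp_expression):
        expr, labels = pc_cp_expression
        only_pc = labels.index[labels == "PC"]
        with pytest.raises(ValueError, match="CP"):
            train_svm(expr.restrict(samples=only_pc), labels.loc[only_pc], "PC", "CP")

    def test_model_round_trip(self, trained, tmp_path):
        model, _, _ = trained
        save_model(model, tmp_path / "model.txt")
        back = load_model(tmp_path / "model.txt")
        assert back.panel == model.panel
        np.testing.assert_allclose(back.w, model.w)
        assert back.w0 == model.w0 and back.C == model.C
        assert (back.positive_label, back.negative_label) == ("PC", "CP")
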