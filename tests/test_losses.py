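"""Loss components against hand-computed values and brute-force oracles."""

import numpy as np
import pytest

import survite.losses as L
from survite._autodiff import Tensor
from survite.knowledge import Effect

P, Z, U = Effect.POSITIVE, Effect.ZERO, Effect.UNKNOWN


class TestFactualLoss:
    def test_perfect_prediction_is_zero(self):
        assert L.factual_loss([10.0], [1], [1], [10.0]).item() == 0.0

    def test_observed_events_use_absolute_error_with_arm_mean(self):
        # two treated records: |10-10| and |7-9| averaged over the arm
        got = L.factual_loss([10.0, 7.0], [1, 1], [1, 1], [10.0, 9.0])
        assert got.item() == pytest.approx(1.0, abs=1e-12)

    def test_censored_record_above_censoring_time_is_free(self):
        assert L.factual_loss([10.0], [0], [0], [12.0]).item() == 0.0
        # below the censoring time the hinge penalizes the shortfall
        got = L.factual_loss([10.0], [0], [0], [6.0])
        assert got.item() == pytest.approx(4.0, abs=1e-12)

    def test_arms_normalized_separately(self):
        got = L.factual_loss([10.0, 4.0, 6.0], [1, 1, 1], [1, 0, 0],
                             [8.0, 5.0, 5.0])
        assert got.item() == pytest.approx(2.0 + (1.0 + 1.0) / 2, abs=1e-12)


class TestMMD:
    def test_identical_samples_give_zero(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        assert L.mmd2_rbf(x, x, bandwidth=1.0).item() == pytest.approx(0, abs=1e-12)

    def test_two_point_closed_form(self):
        got = L.mmd2_rbf(np.array([[0.0]]), np.array([[1.0]]), bandwidth=1.0)
        assert got.item() == pytest.approx(2 - 2 * np.exp(-0.5), rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(7, 2))
        assert L.mmd2_rbf(a, b, 0.7).item() == pytest.approx(
            L.mmd2_rbf(b, a, 0.7).item(), rel=1e-12)

    @pytest.mark.parametrize("n1,n0", [(3, 4), (20, 15), (1, 20)])
    def test_matches_brute_force_double_loop(self, n1, n0):
        rng = np.random.default_rng(n1 * 31 + n0)
        a, b = rng.normal(size=(n1, 4)), rng.normal(size=(n0, 4))
        sigma = 1.3
        k = lambda u, v: np.exp(-np.sum((u - v) ** 2) / (2 * sigma**2))
        brute = (np.mean([[k(x, y) for y in a] for x in a])
                 + np.mean([[k(x, y) for y in b] for x in b])
                 - 2 * np.mean([[k(x, y) for y in b] for x in a]))
        assert L.mmd2_rbf(a, b, sigma).item() == pytest.approx(brute, abs=1e-12)

    def test_empty_arm_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            out = L.ipm_distance(np.zeros((0, 2)), np.ones((3, 2)))
        assert out.item() == 0.0

    def test_sinkhorn_separates_distant_samples(self):
        a = np.zeros((4, 2))
        b = np.ones((4, 2)) * 3
        near = L.sinkhorn_wasserstein(a, a + 0.01).item()
        far = L.sinkhorn_wasserstein(a, b).item()
        assert far > near >= 0


class TestTreatmentCE:
    def test_hand_values(self):
        assert L.treatment_ce([0.5, 0.5], [1, 0]).item() == pytest.approx(
            np.log(2), rel=1e-12)
        assert L.treatment_ce([0.9], [0]).item() == pytest.approx(
            -np.log(0.1), rel=1e-12)

    def test_confident_correct_probabilities_vanish(self):
        assert L.treatment_ce([1 - 1e-12, 1e-12], [1, 0]).item() < 1e-10


class TestPriorLosses:
    def test_worked_four_record_batch(self):
        """One positive-region treated record with an over-shooting control
        prediction and one zero-region control record with an off-label
        counterfactual; two unknowns contribute nothing."""
        time = [8.0, 6.0, 5.0, 9.0]
        event = [1, 1, 1, 0]
        treat = [1, 0, 0, 1]
        ycf = [10.0, 9.0, 123.0, 456.0]   # unknown entries are ignored
        mem = [P, Z, U, U]
        out = L.prior_losses(time, event, treat, ycf, mem,
                             normalized_omega=False)
        assert out["l13"].item() == pytest.approx(0.5, abs=1e-12)   # (1/4)*2
        assert out["l21"].item() == pytest.approx(0.75, abs=1e-12)  # (1/4)*3
        assert out["lcp"].item() == pytest.approx(1.25, abs=1e-12)
        for k in ("l11", "l12", "l22"):
            assert out[k].item() == 0.0

    def test_satisfied_lower_bound_contributes_nothing(self):
        out = L.prior_losses([10.0], [1], [0], [12.0], [P])
        assert out["lcp"].item() == 0.0

    def test_censored_treated_positive_region_is_uninformative(self):
        out = L.prior_losses([10.0], [0], [1], [1.0], [P])
        assert out["lcp"].item() == 0.0

    def test_zero_region_censored_uses_lower_bound_hinge(self):
        out = L.prior_losses([10.0], [0], [1], [7.0], [Z],
                             normalized_omega=False)
        assert out["l22"].item() == pytest.approx(3.0, abs=1e-12)
        assert out["l21"].item() == 0.0

    def test_normalized_variant_divides_by_group_sizes(self):
        time = [10.0, 10.0]
        out_raw = L.prior_losses(time, [1, 1], [0, 0], [4.0, 4.0], [P, P],
                                 normalized_omega=False)
        out_norm = L.prior_losses(time, [1, 1], [0, 0], [4.0, 4.0], [P, P],
                                  normalized_omega=True)
        assert out_raw["l11"].item() == pytest.approx(12.0)   # (2/2)*(6+6)
        assert out_norm["l11"].item() == pytest.approx(6.0)   # inner mean

    def test_hinge_monotonicity_in_counterfactual_prediction(self):
        vals = [2.0, 5.0, 9.0, 15.0]
        l11 = [L.prior_losses([10.0], [1], [0], [v], [P])["l11"].item()
               for v in vals]
        assert all(a >= b for a, b in zip(l11, l11[1:]))
        l13 = [L.prior_losses([10.0], [1], [1], [v], [P])["l13"].item()
               for v in vals]
        assert all(a <= b for a, b in zip(l13, l13[1:]))

    def test_all_unknown_batch_has_zero_penalty(self):
        out = L.prior_losses([5.0, 6.0], [1, 1], [1, 0], [1.0, 1.0], [U, U])
        assert out["lcp"].item() == 0.0


class TestTotalLoss:
    def _parts(self):
        return (Tensor(3.0), Tensor(0.5), Tensor(0.7), Tensor(1.1))

    def test_mode_assembly(self):
        f, i, c, l = self._parts()
        assert L.total_loss(f, i, c, l, 2.0, 10.0, "csa").item() == \
            pytest.approx(3 + 2 * 0.5)
        assert L.total_loss(f, i, c, l, 2.0, 10.0, "csa_dragonnet").item() == \
            pytest.approx(3 + 1 + 7)
        assert L.total_loss(f, i, c, l, 2.0, 10.0, "cdnepk").item() == \
            pytest.approx(3 + 1 + 7 + 1.1)

    def test_weightless_reduction_to_factual(self):
        f, i, c, _ = self._parts()
        assert L.total_loss(f, i, c, Tensor(0.0), 0.0, 0.0, "cdnepk").item() \
            == pytest.approx(3.0)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            L.total_loss(*self._parts(), 1.0, 1.0, "dragonnet")


class TestGradients:
    """Each loss component must agree with central finite differences."""

    def _num_grad(self, f, x, h=1e-6):
        g = np.zeros_like(x)
        for k in range(x.size):
            old = x[k]
            x[k] = old + h
            fp = f()
            x[k] = old - h
            fm = f()
            x[k] = old
            g[k] = (fp - fm) / (2 * h)
        return g

    def test_factual_loss_gradient(self):
        y = np.array([8.3, 11.0, 2.0, 7.7])
        f = lambda: L.factual_loss([10, 7, 3, 8], [1, 0, 1, 1],
                                   [1, 0, 1, 0], y).item()
        yt = Tensor(y.copy(), requires_grad=True)
        out = L.factual_loss([10, 7, 3, 8], [1, 0, 1, 1], [1, 0, 1, 0], yt)
        out.backward()
        np.testing.assert_allclose(yt.grad, self._num_grad(f, y), atol=1e-6)

    def test_mmd_gradient(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 2))
        b = rng.normal(size=(5, 2))
        f = lambda: L.mmd2_rbf(a, b, 0.9).item()
        at = Tensor(a.copy(), requires_grad=True)
        out = L.mmd2_rbf(at, b, 0.9)
        out.backward()
        np.testing.assert_allclose(at.grad.ravel(),
                                   self._num_grad(f, a.ravel()), atol=1e-6)

    def test_treatment_ce_gradient(self):
        p = np.array([0.2, 0.7, 0.5])
        f = lambda: L.treatment_ce(p, [0, 1, 1]).item()
        pt = Tensor(p.copy(), requires_grad=True)
        L.treatment_ce(pt, [0, 1, 1]).backward()
        np.testing.assert_allclose(pt.grad, self._num_grad(f, p), atol=1e-6)

    def test_prior_loss_gradient(self):
        y = np.array([9.0, 5.0, 12.0, 3.0])
        mem = [P, P, Z, Z]
        args = ([10, 8, 6, 7], [1, 0, 1, 0], [0, 0, 1, 1])
        f = lambda: L.prior_losses(*args, y, mem)["lcp"].item()
        yt = Tensor(y.copy(), requires_grad=True)
        L.prior_losses(*args, yt, mem)["lcp"].backward()
        np.testing.assert_allclose(yt.grad, self._num_grad(f, y), atol=1e-6)
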