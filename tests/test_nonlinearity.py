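"""Equal-spike binning, double-sigmoid fitting, and LN prediction."""

import numpy as np
import pytest

import elstim as el
from elstim.nonlinearity import oriented_axis, sigmoid_neg, sigmoid_pos


def _symmetric_toy_ensemble(n=3000, seed=0, sigma=100.0):
    """2-electrode ensemble spiking through a known double sigmoid along e0."""
    rng = np.random.default_rng(seed)
    S = rng.normal(0, sigma, size=(n, 2))
    x = S[:, 0]
    p = sigmoid_pos(x, 0.9, 0.03, 150.0) + sigmoid_neg(x, 0.9, 0.03, -150.0)
    resp = (rng.random(n) < np.clip(p, 0, 1)).astype(int)
    return el.SpikeTriggeredEnsemble(S, resp), p


class TestBinProjections:
    def test_equal_spike_counts_per_bin(self):
        """30 spike-eliciting stimuli spread over the positive side split into
        15 bins of exactly 2 spikes."""
        x = np.linspace(5, 300, 30)
        S = np.column_stack([x, np.zeros(30)])
        extra = np.column_stack([np.linspace(1, 299, 100), np.zeros(100)])
        ens = el.SpikeTriggeredEnsemble(
            np.vstack([S, extra]), np.r_[np.ones(30, int), np.zeros(100, int)]
        )
        erf = el.estimate_erfs(ens, np.array([1.0, 0.0]))
        pos, neg = el.bin_projections(ens, erf, n_bins_per_side=15)
        assert neg is None
        np.testing.assert_array_equal(pos.n_spikes, np.full(15, 2))
        assert pos.n_stimuli.sum() == 130

    def test_identical_projections_collapse_to_single_bin(self):
        S = np.tile([50.0, 0.0], (40, 1))
        resp = np.r_[np.ones(10, int), np.zeros(30, int)]
        ens = el.SpikeTriggeredEnsemble(S, resp)
        erf = el.estimate_erfs(ens, np.array([1.0, 0.0]))
        pos, _ = el.bin_projections(ens, erf, n_bins_per_side=15)
        assert pos.bin_centers.size == 1
        assert pos.probabilities[0] == pytest.approx(0.25)

    def test_too_few_spikes_reduce_bins_with_warning(self):
        rng = np.random.default_rng(1)
        S = np.column_stack([rng.normal(0, 100, 200), np.zeros(200)])
        resp = (S[:, 0] > 120).astype(int)  # only a handful of spikes
        ens = el.SpikeTriggeredEnsemble(S, resp)
        erf = el.estimate_erfs(ens, np.array([1.0, 0.0]))
        with pytest.warns(UserWarning, match="reducing bin count"):
            pos, _ = el.bin_projections(ens, erf, n_bins_per_side=15)
        assert pos.bin_centers.size <= resp.sum()

    def test_binned_probabilities_track_generating_sigmoid(self):
        """Per-bin probabilities fall within 3 binomial standard errors of the
        generating nonlinearity at the bin centers for >= 27 of 30 bins."""
        ens, _ = _symmetric_toy_ensemble(n=6000, seed=2)
        erf = el.estimate_erfs(ens, np.array([1.0, 0.0]))
        pos, neg = el.bin_projections(ens, erf)
        ok = 0
        total = 0
        for b, f, c in ((pos, sigmoid_pos, 150.0), (neg, sigmoid_neg, -150.0)):
            truth = f(b.bin_centers, 0.9, 0.03, c) + (
                sigmoid_neg(b.bin_centers, 0.9, 0.03, -150.0)
                if f is sigmoid_pos
                else sigmoid_pos(b.bin_centers, 0.9, 0.03, 150.0)
            )
            se = np.sqrt(np.clip(truth * (1 - truth), 1e-4, None) / b.n_stimuli)
            ok += int(np.sum(np.abs(b.probabilities - truth) <= 3 * se))
            total += b.bin_centers.size
        assert total == 30
        assert ok >= 27


class TestFitDoubleSigmoid:
    def test_noiseless_parameters_recovered(self):
        """Exact samples of the rising sigmoid are recovered to 3 significant
        figures with r2 >= 0.999."""
        x = np.linspace(10, 400, 15)
        pos = el.BinnedProbability(
            bin_centers=x,
            probabilities=sigmoid_pos(x, 0.9, 0.03, 150.0),
            n_stimuli=np.full(15, 100),
            n_spikes=np.full(15, 10),
            side="positive",
        )
        xm = -x[::-1]
        neg = el.BinnedProbability(
            bin_centers=xm,
            probabilities=sigmoid_neg(xm, 0.8, 0.025, -140.0),
            n_stimuli=np.full(15, 100),
            n_spikes=np.full(15, 10),
            side="negative",
        )
        fit = el.fit_double_sigmoid((pos, neg))
        assert fit.a_plus == pytest.approx(0.9, rel=1e-3)
        assert fit.b_plus == pytest.approx(0.03, rel=1e-3)
        assert fit.c_plus == pytest.approx(150.0, rel=1e-3)
        assert fit.a_minus == pytest.approx(0.8, rel=1e-3)
        assert fit.c_minus == pytest.approx(-140.0, rel=1e-3)
        assert fit.r2 >= 0.999

    def test_half_saturation_at_threshold(self):
        fit = el.DoubleSigmoid(0.8, 0.03, 150.0, 0.8, 0.03, -150.0, r2=1.0)
        assert fit.n_plus(150.0) == pytest.approx(0.4)
        assert fit.n_minus(-150.0) == pytest.approx(0.4)

    def test_fitted_curves_monotone_over_observed_range(self, single_run):
        sig = single_run.model_full.sigmoid
        x = np.linspace(-500, 500, 1001)
        assert np.all(np.diff(sig.n_plus(x)) >= -1e-12)
        assert np.all(np.diff(sig.n_minus(x)) <= 1e-12)


class TestPredict:
    def _model(self, a_plus=0.8, off_side="summed", baseline=0.0):
        sig = el.DoubleSigmoid(a_plus, 0.03, 150.0, 0.8, 0.03, -150.0, r2=1.0)
        return el.LNModel(
            w_plus=np.array([1.0, 0.0]),
            w_minus=np.array([-1.0, 0.0]),
            sigmoid=sig,
            v1=np.array([1.0, 0.0]),
            baseline=baseline,
            off_side=off_side,
        )

    def test_orthogonal_stimulus_gives_central_offsets(self):
        model = self._model()
        p = model.predict(np.array([[0.0, 50.0]]))[0]
        expected = model.sigmoid.n_plus(0.0) + model.sigmoid.n_minus(0.0)
        assert p == pytest.approx(expected)

    def test_half_saturation_probability(self):
        """At the threshold projection with a+ = 0.8 the prediction is 0.40
        plus the (negligible) off-side floor."""
        model = self._model(a_plus=0.8)
        p = model.predict(np.array([[150.0, 0.0]]))[0]
        off = model.sigmoid.n_minus(150.0)  # ~ 1e-4
        assert p == pytest.approx(0.40 + off, abs=1e-6)
        assert p == pytest.approx(0.40, abs=1e-3)

    def test_scale_consistency(self):
        """Scaling stimuli and thresholds by k while scaling gains by 1/k
        leaves predictions unchanged."""
        k = 3.7
        m1 = self._model()
        sig2 = el.DoubleSigmoid(0.8, 0.03 / k, 150.0 * k, 0.8, 0.03 / k, -150.0 * k, r2=1.0)
        m2 = el.LNModel(
            w_plus=m1.w_plus, w_minus=m1.w_minus, sigmoid=sig2, v1=m1.v1
        )
        S = np.random.default_rng(4).normal(0, 120, size=(50, 2))
        np.testing.assert_allclose(m1.predict(S), m2.predict(k * S), rtol=1e-10)

    def test_mean_prediction_matches_empirical_rate(self, single_run):
        """On a fresh ensemble from the same cell, the mean predicted
        probability agrees with the empirical spike rate within 2 SEs."""
        cell = single_run.cell
        sigma = single_run.ensemble.sigma
        fresh = el.sample_white_noise(2000, 20, sigma, repeats=3, seed=777)
        rec = el.simulate_responses(cell, fresh, seed=778)
        p = single_run.model_full.predict(fresh.amplitudes)
        rate = rec.responses.short.mean()
        se = np.sqrt(rate * (1 - rate) / rec.responses.short.size)
        assert abs(p.mean() - rate) <= 2 * se + 0.01

    def test_absent_side_contributes_nothing(self):
        sig = el.DoubleSigmoid(0.8, 0.03, 150.0, np.nan, np.nan, np.nan, r2=1.0)
        model = el.LNModel(
            w_plus=np.array([1.0, 0.0]), w_minus=None, sigmoid=sig, v1=np.array([1.0, 0.0])
        )
        assert model.predict(np.array([[150.0, 0.0]]))[0] == pytest.approx(0.4)

    def test_oriented_axis_gives_negative_cathodic_thresholds(self):
        """The negative-side projection axis is oriented with v1, so net
        cathodic stimuli project negatively (thresholds come out c- < 0)."""
        v1 = np.array([1.0, 0.0])
        u_m = oriented_axis(np.array([-5.0, 0.0]), v1)
        np.testing.assert_allclose(u_m, [1.0, 0.0])
        cathodic = np.array([-200.0, 0.0])
        assert cathodic @ u_m < 0


class TestFit2D:
    def test_surface_flat_along_irrelevant_axis(self):
        """For a separable ground truth (no dependence on the second axis) the
        fitted surface varies little along x2 at fixed x1."""
        array = el.default_array()
        cell = el.make_cell(array, [1.75, 1.75], seed=0)
        ens = el.sample_white_noise(10_000, 20, 100.0, seed=7)
        rec = el.simulate_responses(cell, ens, seed=8)
        sens = el.SpikeTriggeredEnsemble(ens.amplitudes, rec.responses.short, mask=ens.mask)
        spec = el.spike_triggered_cov(sens)
        v1, v2 = spec.eigenvectors[:, 0], spec.eigenvectors[:, 5]
        m2 = el.fit_2d(sens, v1, v2)
        row_sds = []
        for i in range(m2.prob_grid.shape[0]):
            vals = m2.prob_grid[i, m2.support[i]]
            if vals.size >= 3:
                row_sds.append(vals.std())
        assert np.mean(row_sds) <= 0.05

    def test_spline_reproduces_grid_nodes(self):
        rng = np.random.default_rng(5)
        S = rng.normal(0, 100, size=(5000, 3))
        resp = (rng.random(5000) < 0.3).astype(int)
        ens = el.SpikeTriggeredEnsemble(S, resp)
        v1 = np.array([1.0, 0, 0])
        v2 = np.array([0, 1.0, 0])
        m2 = el.fit_2d(ens, v1, v2, grid_resolution=8, min_count=5)
        c1 = 0.5 * (m2.x1_edges[:-1] + m2.x1_edges[1:])
        c2 = 0.5 * (m2.x2_edges[:-1] + m2.x2_edges[1:])
        node_vals = m2._spline(c1, c2)
        np.testing.assert_allclose(node_vals, m2.prob_grid, atol=1e-8)

    def test_surface_captures_suppressive_axis(self):
        """For a genuinely 2-D ground truth (Gaussian-bump suppression along a
        second axis) the fitted surface is visibly suppressed at large |x2|
        relative to x2 ~ 0 in the driven region of x1 — structure the 1-D
        model cannot represent."""
        array = el.default_array()
        hits = 0
        for seed in range(5):
            cell = el.make_cell(array, [1.75, 1.75], seed=seed)
            w = cell.w_true_plus
            e = np.zeros(20)
            e[15] = 1.0
            e -= (e @ w) * w
            e /= np.linalg.norm(e)
            v2_true = e  # orthogonal suppressive axis
            cell.suppressive_axis = (v2_true, 0.9, 70.0)
            ens = el.sample_white_noise(12_000, 20, 100.0, seed=100 + seed)
            rec = el.simulate_responses(cell, ens, seed=200 + seed)
            sens = el.SpikeTriggeredEnsemble(ens.amplitudes, rec.responses.short, mask=ens.mask)
            m2 = el.fit_2d(sens, w, v2_true, grid_resolution=9, min_count=30)
            x2_centers = 0.5 * (m2.x2_edges[:-1] + m2.x2_edges[1:])
            x1_centers = 0.5 * (m2.x1_edges[:-1] + m2.x1_edges[1:])
            driven = x1_centers > 100.0  # rows where the cell is driven
            near = np.abs(x2_centers) < 70.0
            far = np.abs(x2_centers) > 140.0
            sup = m2.support[driven]
            grid = m2.prob_grid[driven]
            centre = grid[:, near][sup[:, near]]
            flank = grid[:, far][sup[:, far]]
            if centre.size and flank.size:
                hits += centre.mean() > flank.mean() + 0.1
        assert hits >= 4
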