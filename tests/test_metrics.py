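import numpy as np
import pytest

from grinsim import metrics as met
from grinsim.extract import ROIRecord, Box
from grinsim.stats import PermutationSpec
from _oracles import adjacent_fraction_enumeration, purity_via_statsmodels


def make_roi(roi_id, dff, snr=20.0, r_um=0.0):
    return ROIRecord(
        roi_id=roi_id,
        box=Box(0, 2, 0, 2),
        centroid_px=(0.5, 0.5),
        centroid_um_r=r_um,
        trace_f=dff,
        dff=dff,
        peak_snr=snr,
        contributing_sources=np.array([0]),
    )


class TestExpectedPairCorrelation:
    def test_three_trace_brute_force(self, rng):
        tr = rng.normal(size=(3, 300))
        thr, mean, sd = met.expected_pair_correlation([tr])
        cors = np.array(
            [np.corrcoef(tr[i], tr[j])[0, 1] for i, j in [(0, 1), (0, 2), (1, 2)]]
        )
        assert mean == pytest.approx(cors.mean(), abs=1e-12)
        assert sd == pytest.approx(cors.std(ddof=1), abs=1e-12)
        assert thr == pytest.approx(cors.mean() + 3 * cors.std(ddof=1), abs=1e-12)

    def test_independent_traces_threshold_near_3sd(self, rng):
        tr = rng.normal(size=(40, 500))
        thr, mean, sd = met.expected_pair_correlation([tr])
        assert abs(mean) < 0.01
        assert thr == pytest.approx(mean + 3 * sd)

    def test_zero_variance_pairs_threshold_equals_mean(self):
        t = np.sin(np.linspace(0, 20, 200))
        fovs = [np.stack([t, t]), np.stack([t, -t + 0.0])]
        # pair correlations are exactly +1 and -1 -> handcheck via pooled sd
        thr, mean, sd = met.expected_pair_correlation(fovs)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(np.std([1.0, -1.0], ddof=1), abs=1e-9)

    def test_single_pair_errors(self):
        t = np.random.default_rng(0).normal(size=(2, 100))
        with pytest.raises(ValueError):
            met.expected_pair_correlation([t[:1]])


class TestAdjacentPairs:
    def _setup(self, rng):
        # 4 ROIs: two adjacent clusters, traces with known correlations
        pos = np.array([[0.0, 0.0], [10.0, 0.0], [100.0, 0.0], [108.0, 0.0]])
        base = rng.normal(size=400)
        traces = np.stack(
            [
                base,
                base + rng.normal(0, 0.1, 400),  # strongly correlated pair
                rng.normal(size=400),
                rng.normal(size=400),  # uncorrelated adjacent pair
            ]
        )
        snrs = [30.0, 25.0, 18.0, 12.0]
        rois = [make_roi(i, traces[i], snr=snrs[i]) for i in range(4)]
        pairs = met.build_pairs(rois, pos)
        corr = np.corrcoef(traces)
        return rois, pairs, pos, corr, snrs

    def test_matches_exhaustive_enumeration(self, rng):
        rois, pairs, pos, corr, snrs = self._setup(rng)
        snrs_by_id = {r.roi_id: r.peak_snr for r in rois}
        for cutoff in (0.0, 15.0, 20.0, 28.0):
            res = met.adjacent_pair_analysis(
                pairs, snrs_by_id, threshold=0.5, snr_grid=(cutoff,)
            )
            above, total = adjacent_fraction_enumeration(
                pos, corr, snrs, 0.5, cutoff
            )
            assert res["n_above"][0] == above
            assert res["n_total"][0] == total
            if total:
                assert res["fraction"][0] == pytest.approx(above / total)
            else:
                assert np.isnan(res["fraction"][0])

    def test_single_roi_no_pairs_missing(self):
        res = met.adjacent_pair_analysis([], {0: 20.0}, 0.5, snr_grid=(0,))
        assert np.isnan(res["fraction"][0])

    def test_alternative_adjacency_30um(self, rng):
        rois, pairs, pos, corr, snrs = self._setup(rng)
        snrs_by_id = {r.roi_id: r.peak_snr for r in rois}
        res25 = met.adjacent_pair_analysis(pairs, snrs_by_id, 0.5, (0,), 25.0)
        res30 = met.adjacent_pair_analysis(pairs, snrs_by_id, 0.5, (0,), 30.0)
        # the 100/108 µm pair is 8 µm apart -> included in both; the two
        # clusters are adjacent only internally
        assert res30["n_total"][0] >= res25["n_total"][0]

    def test_total_pairs_monotone_in_cutoff(self, rng):
        rois, pairs, pos, corr, snrs = self._setup(rng)
        snrs_by_id = {r.roi_id: r.peak_snr for r in rois}
        res = met.adjacent_pair_analysis(
            pairs, snrs_by_id, 0.5, snr_grid=(0, 10, 15, 20, 25, 30)
        )
        assert np.all(np.diff(res["n_total"]) <= 0)


class TestPurity:
    def test_single_source_purity_one(self, rng):
        x = rng.normal(size=300)
        pm = met.purity_glm(2.5 * x + 1.0, x[None, :])
        assert pm.purity == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "coefs,expected", [((1.0, 1.0), 0.5), ((3.0, 1.0), 0.9)]
    )
    def test_purity_formula_arithmetic(self, rng, coefs, expected):
        x = rng.normal(size=(2, 500))
        y = coefs[0] * x[0] + coefs[1] * x[1] + 0.3
        pm = met.purity_glm(y, x)
        assert pm.coefficients == pytest.approx(np.array(coefs), abs=1e-10)
        assert pm.purity == pytest.approx(expected, abs=1e-10)

    def test_exact_recovery_and_statsmodels_cross_check(self, rng):
        x = rng.normal(size=(2, 400))
        y = 0.8 * x[0] + 0.2 * x[1] + 5.0
        pm = met.purity_glm(y, x)
        assert pm.coefficients == pytest.approx([0.8, 0.2], abs=1e-8)
        assert pm.intercept == pytest.approx(5.0, abs=1e-8)
        assert pm.purity == pytest.approx(0.64 / 0.68, abs=1e-8)
        a_sm, purity_sm = purity_via_statsmodels(y, x)
        assert pm.coefficients == pytest.approx(a_sm, abs=1e-8)
        assert pm.purity == pytest.approx(purity_sm, abs=1e-10)

    def test_collinear_sources_warn_minimum_norm(self, rng):
        x = rng.normal(size=300)
        with pytest.warns(UserWarning, match="collinear"):
            pm = met.purity_glm(2.0 * x, np.stack([x, x]))
        assert pm.coefficients == pytest.approx([1.0, 1.0], abs=1e-8)

    def test_regressor_rescaling_inverts_coefficient(self, rng):
        # rescaling a regressor rescales its coefficient inversely; the
        # purity index is therefore scale-sensitive by construction, which
        # is why all sources enter on the common ground-truth trace scale
        x = rng.normal(size=(2, 400))
        y = 3.0 * x[0] + 1.0 * x[1]
        pm1 = met.purity_glm(y, x)
        pm2 = met.purity_glm(y, np.stack([x[0] * 0.5, x[1]]))
        assert pm2.coefficients[0] == pytest.approx(
            pm1.coefficients[0] / 0.5, abs=1e-8
        )
        a = pm2.coefficients
        assert pm2.purity == pytest.approx(max(a**2) / np.sum(a**2), abs=1e-12)


class TestFirstSource:
    def test_identical_trace_gives_one(self, rng):
        x = rng.normal(size=(3, 200))
        c, j = met.first_source_correlation(x[1], x)
        assert c == pytest.approx(1.0)
        assert j == 1

    def test_three_source_enumeration(self, rng):
        x = rng.normal(size=(3, 500))
        y = x[0] * 0.2 + x[2] * 0.9 + rng.normal(0, 0.1, 500)
        c, j = met.first_source_correlation(y, x)
        cors = [np.corrcoef(y, x[k])[0, 1] for k in range(3)]
        assert j == int(np.argmax(cors))
        assert c == pytest.approx(max(cors), abs=1e-12)

    def test_no_sources_error(self):
        with pytest.raises(ValueError):
            met.first_source_correlation(np.ones(10), np.empty((0, 10)))


class TestRadialTrend:
    def test_constant_ys(self):
        t = met.radial_trend(np.arange(20.0), np.full(20, 3.0))
        assert t.slope == 0.0
        assert t.p_slope > 0.9

    def test_exact_line(self):
        x = np.linspace(0, 10, 30)
        t = met.radial_trend(x, 2.0 * x + 1.0)
        assert t.slope == pytest.approx(2.0, abs=1e-12)
        assert t.intercept == pytest.approx(1.0, abs=1e-12)
        assert t.p_slope < 1e-10

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            met.radial_trend(np.ones(10), np.arange(10.0))

    def test_restrict_common_range(self):
        x = np.concatenate([np.linspace(0, 50, 30), np.linspace(100, 200, 30)])
        y = 0.01 * x + np.sin(x)
        t = met.radial_trend(x, y, restrict_r_max=60.0)
        assert t.n == 30
        assert t.r_max <= 60.0

    def test_wald_ci_coverage_on_gaussian_data(self):
        # 95% CI for the slope covers the truth ~95% of the time
        from scipy import stats as sps

        rng = np.random.default_rng(2024)
        n, reps, covered = 30, 500, 0
        tcrit = sps.t.ppf(0.975, n - 2)
        for _ in range(reps):
            x = rng.uniform(0, 1, n)
            y = 1.5 * x + rng.normal(0, 0.5, n)
            fit = sps.linregress(x, y)
            if abs(fit.slope - 1.5) <= tcrit * fit.stderr:
                covered += 1
        assert 0.93 <= covered / reps <= 0.97
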