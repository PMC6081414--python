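import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import hilbert

from icnvar.features import (
    analytic_phase,
    assemble_feature_vector,
    functional_connectivity,
    inter_icn_variability,
    pair_labels,
    pairwise_features,
    phase_difference_variance,
    phase_synchrony,
    wrap_phase,
)
from icnvar.records import SubjectRecord
from icnvar.timecourses import DEFAULT_ICN_LABELS, TimeSeriesMatrix


def _cos(freq_hz=0.05, tr=2.0, n=400, phase=0.0):
    t = np.arange(n) * tr
    return np.cos(2 * np.pi * freq_hz * t + phase)


def _brute_force_var(x, y, trim_frac=0.05):
    """Textbook reference: explicit per-frame loop, manual wrap, manual variance."""
    hx, hy = hilbert(x), hilbert(y)
    dphi = [
        math.atan2(hx[t].imag, hx[t].real) - math.atan2(hy[t].imag, hy[t].real)
        for t in range(len(x))
    ]
    k = math.ceil(trim_frac * len(dphi))
    dphi = dphi[k: len(dphi) - k]
    wrapped = []
    for d in dphi:
        while d <= -math.pi:
            d += 2 * math.pi
        while d > math.pi:
            d -= 2 * math.pi
        wrapped.append(d)
    m = sum(wrapped) / len(wrapped)
    return sum((w - m) ** 2 for w in wrapped) / (len(wrapped) - 1)


class TestWrapPhase:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.0), (3 * np.pi / 2, -np.pi / 2), (-np.pi, np.pi), (np.pi, np.pi),
         (2 * np.pi, 0.0), (-3.5 * np.pi, np.pi / 2)],
    )
    def test_known_values(self, x, expected):
        assert wrap_phase(x) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-1e6, 1e6))
    def test_congruent_and_in_range(self, x):
        w = float(wrap_phase(x))
        assert -np.pi < w <= np.pi
        assert math.isclose(math.cos(w), math.cos(x), abs_tol=1e-6)
        assert math.isclose(math.sin(w), math.sin(x), abs_tol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            wrap_phase(np.nan)


class TestAnalyticPhase:
    def test_cosine_phase_increment_matches_frequency(self):
        f, tr = 0.05, 2.0
        phi = np.unwrap(analytic_phase(_cos(f, tr, n=1000)))
        inc = np.diff(phi)[100:-100]
        assert np.allclose(inc, 2 * np.pi * f * tr, rtol=0.01)

    def test_quadrature_offset(self):
        t = np.arange(1000) * 2.0
        dphi = analytic_phase(np.sin(0.05 * 2 * np.pi * t)) - analytic_phase(
            np.cos(0.05 * 2 * np.pi * t)
        )
        assert np.allclose(wrap_phase(dphi[100:-100]), -np.pi / 2, atol=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            analytic_phase(np.full(100, 3.0))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            analytic_phase(np.arange(5, dtype=float))


class TestInterIcnVariability:
    def test_identical_series_give_zero(self, rng):
        for _ in range(100):
            x = rng.standard_normal(200)
            assert inter_icn_variability(x, x) < 1e-12

    def test_constant_phase_offset_gives_near_zero(self):
        x = _cos(phase=0.0)
        y = _cos(phase=0.7)
        assert inter_icn_variability(x, y) < 1e-3

    def test_uniform_phase_difference_limit(self, rng):
        """i.i.d. uniform wrapped differences -> variance (2*pi)^2/12 = pi^2/3."""
        dphi = rng.uniform(-np.pi, np.pi, size=100_000)
        assert phase_difference_variance(dphi) == pytest.approx(np.pi**2 / 3, rel=0.02)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal(120) + _cos(n=120)
            y = rng.standard_normal(120) + _cos(n=120)
            assert inter_icn_variability(x, y) == pytest.approx(
                _brute_force_var(x, y), abs=1e-10
            )

    def test_symmetry_exact(self, rng):
        x, y = rng.standard_normal(150), rng.standard_normal(150)
        assert inter_icn_variability(x, y) == inter_icn_variability(y, x)

    def test_amplitude_invariance(self, rng):
        x, y = rng.standard_normal(150), rng.standard_normal(150)
        assert inter_icn_variability(3.7 * x, y) == pytest.approx(
            inter_icn_variability(x, y), abs=1e-10
        )
        assert phase_synchrony(x, 0.2 * y) == pytest.approx(
            phase_synchrony(x, y), abs=1e-10
        )

    def test_monotone_in_planted_dispersion(self, rng):
        """Estimated VAR increases with the wrapped-normal dispersion of dphi."""
        t = np.arange(300) * 2.0
        carrier = 2 * np.pi * 0.05 * t
        means = []
        for s2 in (0.01, 0.1, 0.5):
            vals = [
                inter_icn_variability(
                    np.cos(carrier),
                    np.cos(carrier + rng.normal(0, np.sqrt(s2), len(t))),
                )
                for _ in range(50)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_circular_estimator_bounded(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 1000)
        v = phase_difference_variance(dphi, estimator="circular")
        assert 0.0 <= v <= 1.0


class TestComparisonMetrics:
    def test_fc_perfect_and_anti_correlation(self, rng):
        x = rng.standard_normal(100)
        assert functional_connectivity(x, x) == pytest.approx(1.0)
        assert functional_connectivity(x, -x) == pytest.approx(-1.0)

    def test_fc_independent_noise_near_zero(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            if abs(functional_connectivity(r.standard_normal(10_000),
                                           r.standard_normal(10_000))) < 0.05:
                hits += 1
        assert hits >= 19

    def test_fc_constant_rejected(self):
        with pytest.raises(ValueError):
            functional_connectivity(np.ones(10), np.arange(10.0))

    def test_ps_identical_series_unity(self, rng):
        x = rng.standard_normal(200)
        assert phase_synchrony(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_ps_constant_offset_unity(self):
        assert phase_synchrony(_cos(), _cos(phase=0.9)) == pytest.approx(1.0, abs=1e-2)

    def test_ps_uniform_phases_near_zero(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            dphi = r.uniform(-np.pi, np.pi, 10_000)
            if np.abs(np.mean(np.exp(1j * dphi))) < 0.05:
                hits += 1
        assert hits >= 19


def _record(**kw):
    base = dict(subject_id="s", group="adhd", sex="M", age=11.0,
                viq=100.0, piq=100.0, fiq=100.0, mean_fd=0.2)
    base.update(kw)
    return SubjectRecord(**base)


class TestFeatureAssembly:
    @pytest.mark.parametrize("n,expected", [(10, 45), (3, 3), (2, 1)])
    def test_pair_count(self, rng, n, expected):
        tc = TimeSeriesMatrix(
            rng.standard_normal((120, n)) + _cos(n=120)[:, None], 2.0,
            tuple(f"c{i}" for i in range(n)),
        )
        assert len(pairwise_features(tc, "VAR").values) == expected

    def test_var_on_identical_columns_all_zero(self, rng):
        col = rng.standard_normal(120)
        tc = TimeSeriesMatrix(np.tile(col[:, None], (1, 4)), 2.0, ("a", "b", "c", "d"))
        assert np.all(pairwise_features(tc, "VAR").values < 1e-12)

    def test_canonical_pair_order(self):
        labels = pair_labels(["A", "B", "C"])
        assert labels == ("A-B", "A-C", "B-C")
        assert pair_labels(DEFAULT_ICN_LABELS)[0] == "MVN-OVN"
        assert pair_labels(DEFAULT_ICN_LABELS)[-1] == "RFPN-LFPN"

    def test_full_vector_has_51_predictors(self, rng):
        tc = TimeSeriesMatrix(rng.standard_normal((120, 10)) + 1e-3, 2.0, DEFAULT_ICN_LABELS)
        pairs = pairwise_features(tc, "FC")
        vec, names = assemble_feature_vector(pairs, _record())
        assert len(vec) == len(names) == 51
        assert names[45:] == ("viq", "piq", "fiq", "sex", "age", "mean_fd")

    def test_iq_ablation_drops_to_48(self, rng):
        tc = TimeSeriesMatrix(rng.standard_normal((120, 10)) + 1e-3, 2.0, DEFAULT_ICN_LABELS)
        pairs = pairwise_features(tc, "FC")
        vec, names = assemble_feature_vector(pairs, _record(), include_iq=False)
        assert len(vec) == 48 and "fiq" not in names

    def test_motion_ablation_drops_mean_fd(self, rng):
        tc = TimeSeriesMatrix(rng.standard_normal((120, 10)) + 1e-3, 2.0, DEFAULT_ICN_LABELS)
        pairs = pairwise_features(tc, "FC")
        vec, names = assemble_feature_vector(pairs, _record(), include_motion=False)
        assert len(vec) == 50 and "mean_fd" not in names

    def test_sex_encoding_male_one(self, rng):
        tc = TimeSeriesMatrix(rng.standard_normal((120, 2)) + 1e-3, 2.0, ("a", "b"))
        pairs = pairwise_features(tc, "FC")
        vec_m, names = assemble_feature_vector(pairs, _record(sex="M"))
        vec_f, _ = assemble_feature_vector(pairs, _record(sex="F"))
        i = names.index("sex")
        assert vec_m[i] == 1.0 and vec_f[i] == 0.0

    def test_missing_covariate_raises(self, rng):
        tc = TimeSeriesMatrix(rng.standard_normal((120, 2)) + 1e-3, 2.0, ("a", "b"))
        pairs = pairwise_features(tc, "FC")
        with pytest.raises(ValueError, match="mean_fd"):
            assemble_feature_vector(pairs, _record(mean_fd=None))

    def test_failing_pair_named(self):
        data = np.column_stack([_cos(n=120), np.ones(120)])
        tc = TimeSeriesMatrix(data, 2.0, ("good", "flat"))
        with pytest.raises(ValueError, match="good-flat"):
            pairwise_features(tc, "VAR")
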