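"""Phenotype parameters: closed-form checks, brute-force oracles,
invariants (telescoping, rotation, scale covariance)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cosine_profile
from mdcyto import (DataError, DeformationTrace, FEATURE_NAMES,
                    circular_moving_average, compute_phenotype,
                    deformability_metrics, kinetics_metrics,
                    morphology_metrics, size_metrics)
from mdcyto.core import RadialProfile
from mdcyto.registry import BASELINE_FEATURES, REGISTRY, category_features


def brute_force_ma(r, window):
    """Independent direct-summation trailing moving average."""
    n = len(r)
    return np.array([np.mean([r[(i - k) % n] for k in range(window + 1)])
                     for i in range(n)])


def brute_force_morphology(r, window):
    """Direct implementation of the morphology sum."""
    ma = brute_force_ma(r, window)
    return sum(abs(r[i] - ma[i]) for i in range(len(r)))


def make_trace(D, dt=1.0):
    D = np.asarray(D, float)
    lh = np.full(len(D), 10.0)
    return DeformationTrace(t_us=np.arange(len(D)) * dt,
                            l_vertical=D * lh, l_horizontal=lh)


class TestSizeMetrics:
    def test_circle_closed_forms(self):
        s = size_metrics(cosine_profile(r0=10, eps=0.0))
        assert s.mean_diameter == pytest.approx(20.0, abs=1e-9)
        assert s.area == pytest.approx(np.pi * 100, rel=1e-3)
        assert s.equivalent_diameter == pytest.approx(20.0, rel=5e-4)
        assert s.perimeter == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_ellipse_area(self):
        th = np.deg2rad(np.arange(360))
        r = (20 * 10) / np.sqrt((20 * np.cos(th)) ** 2
                                + (10 * np.sin(th)) ** 2)
        s = size_metrics(RadialProfile(r))
        assert s.area == pytest.approx(np.pi * 200, rel=5e-3)

    def test_scaling_law(self):
        p = cosine_profile(r0=12, k=7, eps=0.04)
        s1 = size_metrics(p)
        s2 = size_metrics(p.scaled(2.0))
        assert s2.mean_diameter == pytest.approx(2 * s1.mean_diameter)
        assert s2.area == pytest.approx(4 * s1.area)


class TestMovingAverage:
    def test_constant_profile(self):
        out = circular_moving_average(np.full(360, 20.0), 30)
        assert np.allclose(out, 20.0)

    def test_impulse_response_window5(self):
        r = np.zeros(360)
        r[100] = 6.0
        out = circular_moving_average(r, 5)
        # trailing window [theta-5, theta]: bins 100..105 see the impulse
        assert np.allclose(out[100:106], 1.0)
        assert np.allclose(np.delete(out, np.s_[100:106]), 0.0)

    @pytest.mark.parametrize("window", [5, 30])
    def test_matches_brute_force_convolution(self, window):
        r = 20 + np.cos(np.deg2rad(12 * np.arange(360)))
        assert np.allclose(circular_moving_average(r, window),
                           brute_force_ma(r, window), atol=1e-12)

    def test_window_bounds(self):
        with pytest.raises(DataError):
            circular_moving_average(np.ones(360), 181)


class TestMorphology:
    def test_perfect_circle(self):
        m = morphology_metrics(cosine_profile(eps=0.0))
        assert m.surface_roughness_5deg == pytest.approx(0.0, abs=1e-9)
        assert m.cell_shape_30deg == pytest.approx(0.0, abs=1e-9)
        assert m.initial_aspect_ratio == pytest.approx(1.0, abs=1e-9)
        assert m.circularity == pytest.approx(1.0, rel=1e-3)

    def test_matches_brute_force_sums(self):
        prof = cosine_profile(r0=20, k=12, eps=0.05, phase=0.4)
        m = morphology_metrics(prof)
        r = prof.r_membrane
        assert m.surface_roughness_5deg == pytest.approx(
            brute_force_morphology(r, 5), abs=1e-9)
        assert m.cell_shape_30deg == pytest.approx(
            brute_force_morphology(r, 30), abs=1e-9)
        # a k=12 ripple survives the 5-deg window far better than the
        # 30-deg window suppresses it relative to roughness
        assert m.surface_roughness_5deg > 0

    def test_rotation_invariance_under_circular_shift(self):
        prof = cosine_profile(r0=20, k=9, eps=0.04, phase=1.1)
        shifted = RadialProfile(np.roll(prof.r_membrane, 37))
        m1, m2 = morphology_metrics(prof), morphology_metrics(shifted)
        assert m1.surface_roughness_5deg == pytest.approx(
            m2.surface_roughness_5deg, abs=1e-9)
        assert m1.cell_shape_30deg == pytest.approx(
            m2.cell_shape_30deg, abs=1e-9)


class TestDeformability:
    def test_undeformed(self):
        d = deformability_metrics(make_trace([1, 1, 1]), 1.0, 20.0)
        assert d == (1.0, 1.0, 0.0, 1 / 20.0, 1.0)

    def test_arithmetic(self):
        d = deformability_metrics(make_trace([1.2, 2.4, 1.8]), 1.2, 10.0)
        assert d.max_deformation == pytest.approx(2.4)
        assert d.relative_deformability == pytest.approx(2.0)
        assert d.deformation_gain == pytest.approx(1.2)
        assert d.final_deformation == pytest.approx(1.8)


class TestKinetics:
    def test_arithmetic_example(self):
        k, flags = kinetics_metrics(make_trace([1, 1.5, 2, 1.6]))
        assert k.mean_deformation_rate == pytest.approx(0.5)
        assert k.mean_relaxation_rate == pytest.approx(-0.4)
        assert k.max_deformation_rate == pytest.approx(0.5)
        assert k.min_deformation_rate == pytest.approx(-0.4)
        assert k.time_to_max_deformation == pytest.approx(2.0)
        assert k.net_deformation_change == pytest.approx(0.6)
        assert flags == []

    def test_constant_trace(self):
        k, flags = kinetics_metrics(make_trace([1.4, 1.4, 1.4]))
        assert k.mean_deformation_rate == 0.0
        assert k.mean_relaxation_rate == 0.0
        assert k.net_deformation_change == 0.0
        assert set(flags) == {"no deformation observed",
                              "no relaxation observed"}

    def test_monotone_rise_flags_no_relaxation(self):
        k, flags = kinetics_metrics(make_trace([1, 1.3, 1.9]))
        assert k.mean_relaxation_rate == 0.0
        assert flags == ["no relaxation observed"]

    def test_nonincreasing_time_rejected(self):
        tr = make_trace([1, 1.5, 2])
        tr.t_us = np.array([0.0, 0.0, 1.0])
        with pytest.raises(DataError):
            kinetics_metrics(tr)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_telescoping_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        D = rng.uniform(1.0, 4.0, size=n)
        k, _ = kinetics_metrics(make_trace(D, dt=float(rng.uniform(0.5, 4))))
        assert k.net_deformation_change == pytest.approx(D[-1] - D[0],
                                                         abs=1e-12)


class TestPhenotypeVector:
    def test_registry_cardinality(self):
        prof = cosine_profile(r0=15, k=10, eps=0.03)
        vec, flags = compute_phenotype(prof, make_trace([1, 1.6, 2.0, 1.7]))
        assert len(vec) == 21
        assert list(vec.index) == list(FEATURE_NAMES)
        remaining = vec.drop(list(BASELINE_FEATURES))
        assert len(remaining) == 19

    def test_category_partition(self):
        names = sum((list(category_features(c))
                     for c in ("size", "deformability", "morphology",
                               "kinetics")), [])
        assert sorted(names) == sorted(FEATURE_NAMES)
        assert [len(category_features(c)) for c in
                ("size", "deformability", "morphology", "kinetics")] == \
            [4, 5, 6, 6]

    def test_provenance_tags(self):
        tags = {p.provenance for p in REGISTRY}
        assert tags == {"paper", "artifact"}

    def test_csv_round_trip(self, tmp_path):
        prof = cosine_profile(r0=15, k=10, eps=0.03)
        vec, _ = compute_phenotype(prof, make_trace([1, 1.6, 2.0, 1.7]))
        path = tmp_path / "one.csv"
        vec.to_frame().T.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back.columns) == list(FEATURE_NAMES)
        assert np.allclose(back.iloc[0].to_numpy(float),
                           vec.to_numpy(float))

    def test_scale_covariance(self):
        prof = cosine_profile(r0=14, k=11, eps=0.05, phase=0.3)
        trace = make_trace([1.0, 1.5, 2.0, 1.8])
        v1, _ = compute_phenotype(prof, trace)
        v2, _ = compute_phenotype(prof.scaled(2.7), trace)
        for name in ("mean_diameter", "perimeter",
                     "surface_roughness_5deg", "cell_shape_30deg"):
            assert v2[name] == pytest.approx(2.7 * v1[name], rel=1e-9)
        assert v2["area"] == pytest.approx(2.7 ** 2 * v1["area"], rel=1e-9)
        for name in ("circularity", "normalized_roughness",
                     "normalized_shape", "initial_aspect_ratio"):
            assert v2[name] == pytest.approx(v1[name], abs=1e-9)
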