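"""Parameters, geometry, exchange rates and the arrangement generator."""

import math

import numpy as np
import pytest

from calspine import (ArrangementConfig, GenerationError,
                      InvalidParameterError, ModelParameters,
                      SpineArrangement, compartment_volumes, coupling_rates,
                      default_parameters, generate_arrangement,
                      two_spine_arrangement)
from calspine.model_core import Geometry


class TestDefaults:
    def test_physiological_values(self):
        p = default_parameters()
        assert p.D == 220.0
        assert p.tau_decay == 0.08
        assert (p.l_n, p.a_s, p.r_s, p.r_d) == (0.5, 0.1, 0.34, 1.0)
        assert p.gamma == 0.11
        assert p.z == 2 and p.F == 96485.0
        assert p.I0 == 0.1 and p.tau_d == 1e-3

    def test_fig2_preset_thresholds(self):
        p = default_parameters("fig2")
        assert p.theta_d == pytest.approx(2e-3)
        assert p.theta_p == pytest.approx(4e-3)

    @pytest.mark.parametrize("bad", [
        {"theta_d": 5e-3},                    # theta_d above theta_p
        {"theta_d": -1e-3},
        {"gamma": 0.0},
        {"gamma": 1.5},
        {"r_d": -1.0},
        {"tau_decay": 0.0},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            ModelParameters(**bad)


class TestVolumesAndRates:
    def test_volumes_match_direct_arithmetic(self, params):
        V_d, V_s = compartment_volumes(params, dx=1.0)
        assert V_d == pytest.approx(math.pi * 1.0 ** 2 * 1.0, rel=1e-12)
        assert V_s == pytest.approx((4 / 3) * math.pi * 0.34 ** 3, rel=1e-12)

    def test_rates_match_independent_oracle(self, params):
        # k_d = 4*220*0.1 / pi = 88/pi; k_s = 1/(V_s/88 + 0.25/440)
        k_d, k_s = coupling_rates(params, dx=1.0)
        assert k_d == pytest.approx(88.0 / math.pi, rel=1e-9)
        V_s = (4 / 3) * math.pi * 0.34 ** 3
        k_s_oracle = 1.0 / (V_s / (4 * 220.0 * 0.1) + 0.5 ** 2 / (2 * 220.0))
        assert k_s == pytest.approx(k_s_oracle, rel=1e-9)

    @pytest.mark.parametrize("dx", [0.1, 0.5, 1.0, 2.0])
    def test_dendritic_extraction_rate_discretization_independent(self, params, dx):
        # k_d * V_d == 4 D a_s regardless of segment length
        k_d, _ = coupling_rates(params, dx)
        V_d, _ = compartment_volumes(params, dx)
        assert k_d * V_d == pytest.approx(4 * params.D * params.a_s, rel=1e-12)

    def test_rates_increase_with_diffusion(self, params):
        rates = [coupling_rates(params.replace(D=D), 1.0) for D in (10, 110, 220, 440)]
        k_ds, k_ss = zip(*rates)
        assert all(np.diff(k_ds) > 0) and all(np.diff(k_ss) > 0)

    def test_zero_diffusion_gives_zero_rates_with_warning(self, params):
        with pytest.warns(RuntimeWarning):
            k_d, k_s = coupling_rates(params.replace(D=0.0), 1.0)
        assert k_d == 0.0 and k_s == 0.0

    def test_nonpositive_dx_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            compartment_volumes(params, dx=0.0)


class TestGeometry:
    def test_from_length(self):
        g = Geometry.from_length(80.0, 0.5)
        assert g.n_segments == 160
        assert g.centers[0] == pytest.approx(0.25)
        assert g.centers[-1] == pytest.approx(79.75)

    def test_inconsistent_segment_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            Geometry(length=10.0, dx=0.5, n_segments=19)


class TestArrangementGenerator:
    @pytest.mark.parametrize("seed", range(100))
    def test_constraints_hold_for_every_seed(self, seed):
        arr = generate_arrangement(seed)
        groups = np.array(arr.groups)
        assert arr.n_spines == 16
        assert (groups == "Stim").sum() == 7
        assert (groups == "Un_in").sum() == 3
        assert (groups == "Un_out").sum() == 6
        start, length = arr.cluster_window
        pos = arr.positions
        inside = (pos > start) & (pos < start + length)
        # exactly the 10 cluster spines in the 7 um window
        assert inside.sum() == 10
        assert set(groups[inside]) == {"Stim", "Un_in"}
        # at least three unstimulated spines on each flank
        assert (groups[pos < start] == "Un_out").sum() >= 3
        assert (groups[pos > start + length] == "Un_out").sum() >= 3
        # density of the cluster section ~1.4 spines/um
        assert round(inside.sum() / length, 1) == 1.4
        assert all(0.3 <= w <= 0.7 for w in arr.initial_weights)

    def test_deterministic_given_seed(self):
        a, b = generate_arrangement(11), generate_arrangement(11)
        assert a == b
        c = generate_arrangement(12)
        assert c.spine_segments != a.spine_segments or c.initial_weights != a.initial_weights

    def test_unsatisfiable_constraints_raise(self):
        with pytest.raises(GenerationError):
            generate_arrangement(0, ArrangementConfig(length=8.0))

    def test_json_roundtrip(self, tmp_path):
        arr = generate_arrangement(3)
        path = tmp_path / "arr.json"
        arr.to_json(path)
        back = SpineArrangement.from_json(path)
        assert back.spine_segments == arr.spine_segments
        assert back.groups == arr.groups
        np.testing.assert_allclose(back.initial_weights, arr.initial_weights)

    def test_mirrored_reflects_positions(self):
        arr = generate_arrangement(5)
        mirrored = arr.mirrored()
        np.testing.assert_allclose(
            np.sort(mirrored.positions),
            np.sort(arr.geometry.length - arr.positions))


class TestTwoSpineArrangement:
    def test_distance_respected(self):
        arr = two_spine_arrangement(distance=2.0)
        assert np.diff(arr.positions)[0] == pytest.approx(2.0)

    def test_distance_must_align_with_grid(self):
        with pytest.raises(InvalidParameterError):
            two_spine_arrangement(distance=0.7)
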