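import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pwpsim.arterial_tree import (
    ArterialSegment,
    ArterialTree,
    HemodynamicConstants,
    WindkesselLoad,
    scale_tree,
    ScaleFactors,
)
from pwpsim.tlm_core import (
    FrequencyGrid,
    SingularLineError,
    combine_bifurcation,
    input_impedance,
    moens_korteweg_speed,
    path_transfer_function,
    poiseuille_resistance,
    reflection_coefficient,
    segment_spectral_props,
    segment_transfer_function,
    tree_dc_impedance,
    tree_input_impedance,
    windkessel_impedance,
    womersley_F10,
)

from conftest import make_segment
from oracles import flat_tree_impedance, womersley_f10_series


class TestWomersleyF10:
    def test_small_alpha_limit(self):
        assert womersley_F10(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_large_alpha_limit(self):
        assert abs(womersley_F10(1e4)) < 1e-3

    # frozen from the power-series oracle (30-digit Bessel evaluation)
    def test_series_oracle_value(self):
        expected = 0.4990102975863977 - 0.3599628391224829j
        assert womersley_F10(3.0) == pytest.approx(expected, abs=1e-10)
        assert womersley_f10_series(3.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 3.0, 8.0, 15.0, 21.0])
    def test_matches_series_everywhere(self, alpha):
        assert womersley_F10(alpha) == pytest.approx(
            womersley_f10_series(alpha), rel=1e-10)

    def test_continuity_across_magnitudes(self):
        a = np.geomspace(1e-6, 1e3, 200)
        v = womersley_F10(a)
        assert np.all(np.isfinite(v))
        assert np.max(np.abs(np.diff(v))) < 0.2

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            womersley_F10(-1.0)


class TestSegmentSpectralProps:
    def test_moens_korteweg_arithmetic(self):
        # E = 4e5 Pa, h/D = 0.1, rho = 1050 kg/m^3 -> ~6.17 m/s
        seg = make_segment(1, load=None, children=(2,), radius=0.5,
                           thickness=0.1, E=4e5)
        assert moens_korteweg_speed(seg, HemodynamicConstants()) == \
            pytest.approx(np.sqrt(4e5 * 0.1 / 1050.0), rel=1e-12)

    def test_high_alpha_z0_limit(self):
        """As F10 -> 0 (large vessel/frequency), |Z0| -> rho c0/(pi r^2)
        times (1 - sigma^2)^(-1/2) = (0.75)^(-1/2) for sigma = 0.5."""
        seg = make_segment(1, children=(2,), radius=1.0, thickness=0.1)
        const = HemodynamicConstants()
        sp = segment_spectral_props(seg, 2e4, const)
        expect = const.rho_si * sp.c0 / (np.pi * 0.01**2) * 0.75**-0.5
        assert abs(sp.Z0) == pytest.approx(expect, rel=1e-2)

    def test_high_alpha_phase_velocity(self):
        """Phase velocity omega/Im(gamma) -> c0 (0.75)^(-1/2)."""
        seg = make_segment(1, children=(2,), radius=1.0, thickness=0.1)
        sp = segment_spectral_props(seg, 2e4)
        assert 2e4 / sp.gamma.imag == pytest.approx(sp.c0 * 0.75**-0.5, rel=1e-2)

    def test_attenuation_nonnegative(self):
        seg = make_segment(1, children=(2,))
        sp = segment_spectral_props(seg, np.linspace(1.0, 500.0, 40))
        assert np.all(sp.gamma.real >= 0)

    def test_dc_refused(self):
        seg = make_segment(1, children=(2,))
        with pytest.raises(ValueError):
            segment_spectral_props(seg, 0.0)

    def test_viscoelastic_phase_rotates(self):
        seg = make_segment(1, children=(2,))
        e0 = segment_spectral_props(seg, 50.0, HemodynamicConstants(phi=0.0))
        e1 = segment_spectral_props(seg, 50.0, HemodynamicConstants(phi=0.2))
        assert np.angle(e1.Z0) == pytest.approx(np.angle(e0.Z0) + 0.1, abs=1e-9)


class TestWindkessel:
    def test_dc_and_infinity_limits(self):
        wk = WindkesselLoad(1e8, 8e8, 2e-9)
        assert windkessel_impedance(wk, 0.0) == pytest.approx(9e8)
        assert windkessel_impedance(wk, 1e9) == pytest.approx(1e8, rel=1e-4)

    def test_hand_complex_value(self):
        # R1=1, R0=2, Cp=1, omega=0.5: 1 + 2/(1+j) = 2 - j
        assert windkessel_impedance(WindkesselLoad(1, 2, 1), 0.5) == \
            pytest.approx(2.0 - 1.0j)


class TestLineEquation:
    Z0 = 5e7 + 5e6j
    GAMMA = 0.1 + 2.0j  # per metre

    def test_matched_line(self):
        assert input_impedance(self.Z0, self.GAMMA, 37.0, self.Z0) == \
            pytest.approx(self.Z0)

    def test_zero_length(self):
        zl = 3e8 - 1e7j
        assert input_impedance(self.Z0, self.GAMMA, 0.0, zl) == pytest.approx(zl)

    def test_quarter_wave_identity(self):
        """Lossless line with gamma*l = j pi/2 transforms ZL into Z0^2/ZL."""
        z0, zl = 5e7, 2e8
        length_cm = 100.0  # 1 m
        gamma = 1j * np.pi / 2.0
        assert input_impedance(z0, gamma, length_cm, zl) == \
            pytest.approx(z0**2 / zl, rel=1e-12)

    def test_bifurcation_parallel(self):
        assert combine_bifurcation(3.0, 6.0) == pytest.approx(2.0)
        z = 4e8 + 1e7j
        assert combine_bifurcation(z, z) == pytest.approx(z / 2.0)

    def test_single_daughter_identity(self):
        z = 4e8 + 1e7j
        assert combine_bifurcation(z) == z

    def test_reflection_limits(self):
        z0 = 5e7
        assert reflection_coefficient(z0, z0) == 0.0
        assert reflection_coefficient(1e30, z0) == pytest.approx(1.0, abs=1e-12)
        assert reflection_coefficient(3 * z0, z0) == pytest.approx(0.5)

    def test_transfer_function_limits(self):
        gamma = 0.05 + 1.2j
        length = 40.0
        assert segment_transfer_function(gamma, length, 0.0) == \
            pytest.approx(np.exp(-gamma * 0.40))
        assert segment_transfer_function(gamma, 0.0, 0.3 + 0.1j) == \
            pytest.approx(1.0)

    def test_closed_end_standing_wave(self):
        beta = 2.0
        length_cm = 50.0
        tf = segment_transfer_function(1j * beta, length_cm, 1.0)
        assert tf == pytest.approx(1.0 / np.cos(beta * 0.5), rel=1e-12)

    def test_as_printed_variant(self):
        gamma, length, G = 0.05 + 1.2j, 40.0, 0.3
        gl = gamma * 0.40
        printed = segment_transfer_function(gamma, length, G, as_printed=True)
        assert printed == pytest.approx((1 + G) / (np.exp(gl) + np.exp(-gl)))


class TestTreeImpedance:
    def test_single_segment_hand_composition(self, single_segment_tree):
        tree = single_segment_tree
        grid = FrequencyGrid(f0=1.2, n_harmonics=10)
        imp = tree_input_impedance(tree, grid)
        seg = tree.segments[1]
        for k, w in enumerate(grid.omega[1:], start=1):
            sp = segment_spectral_props(seg, w)
            zl = windkessel_impedance(seg.terminal_load, w)
            expect = input_impedance(sp.Z0, sp.gamma, seg.length, zl)
            assert imp.z_input[1][k] == pytest.approx(expect, rel=1e-12)

    def test_seven_segment_matches_flat_oracle(self, seven_segment_tree):
        grid = FrequencyGrid(f0=0.4, n_harmonics=20)
        imp = tree_input_impedance(seven_segment_tree, grid)
        for k, w in enumerate(grid.omega[1:], start=1):
            oracle = flat_tree_impedance(seven_segment_tree, w)
            assert abs(imp.z_input[1][k] - oracle) / abs(oracle) < 1e-10

    def test_dc_is_poiseuille_skeleton(self, single_segment_tree):
        tree = single_segment_tree
        const = HemodynamicConstants()
        seg = tree.segments[1]
        expect = poiseuille_resistance(seg, const) + 9e8
        assert tree_dc_impedance(tree, const) == pytest.approx(expect)

    def test_reference_total_peripheral_resistance(self, ref_tree):
        assert tree_dc_impedance(ref_tree) == pytest.approx(1.6e8, rel=1e-6)

    def test_passivity_on_reference(self, ref_tree):
        grid = FrequencyGrid(f0=70 / 60.0, n_harmonics=300)
        imp = tree_input_impedance(ref_tree, grid)
        assert np.all(imp.z_input[ref_tree.root].real > 0)

    def test_e_scaling_scales_c0_sqrt(self, ref_tree):
        s = 1.44
        scaled = scale_tree(ref_tree, ScaleFactors(e_scale=s))
        for i in ref_tree.segments:
            c_a = moens_korteweg_speed(ref_tree.segments[i], HemodynamicConstants())
            c_b = moens_korteweg_speed(scaled.segments[i], HemodynamicConstants())
            assert c_b == pytest.approx(np.sqrt(s) * c_a, rel=1e-12)


def _random_tree(rng: np.random.RandomState) -> ArterialTree:
    n = rng.randint(1, 11)
    segments = {}
    children = {i: [] for i in range(1, n + 1)}
    for i in range(2, n + 1):
        candidates = [p for p in range(1, i) if len(children[p]) < 2]
        parent = int(rng.choice(candidates))
        children[parent].append(i)
    for i in range(1, n + 1):
        load = None
        if not children[i]:
            load = WindkesselLoad(
                R1=float(10 ** rng.uniform(7.5, 8.5)),
                R0=float(10 ** rng.uniform(8.5, 9.8)),
                Cp=float(10 ** rng.uniform(-10, -8.7)),
            )
        segments[i] = ArterialSegment(
            id=i, name=f"s{i}", length=float(rng.uniform(1.0, 40.0)),
            radius=float(rng.uniform(0.1, 0.6)),
            thickness=float(rng.uniform(0.02, 0.1)),
            young_modulus=float(rng.uniform(2e5, 2e6)),
            children=tuple(children[i]), terminal_load=load,
        )
    return ArterialTree(segments.values())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_recursive_equals_brute_force_on_random_trees(seed):
    """The leaf-to-root recursion agrees with an independently written
    flat evaluation on arbitrary small trees (20 frequencies each)."""
    rng = np.random.RandomState(seed)
    tree = _random_tree(rng)
    grid = FrequencyGrid(f0=0.4, n_harmonics=20)
    imp = tree_input_impedance(tree, grid)
    for k, w in enumerate(grid.omega[1:], start=1):
        oracle = flat_tree_impedance(tree, w)
        assert abs(imp.z_input[tree.root][k] - oracle) / abs(oracle) < 1e-10


def test_matched_chain_is_pure_propagation():
    """A chain of identical segments terminated by its own Z0 has zero
    reflection everywhere, so TF = exp(-gamma * L_total)."""
    const = HemodynamicConstants()
    w = 2 * np.pi * 2.0
    proto = make_segment(99, children=(1,))
    sp = segment_spectral_props(proto, w, const)
    # terminal load: a Windkessel that equals Z0 at this frequency is
    # impractical; instead check per-segment: Gamma = 0 when ZL = Z0.
    assert reflection_coefficient(sp.Z0, sp.Z0) == 0.0
    tf = segment_transfer_function(sp.gamma, proto.length, 0.0)
    tf3 = tf**3
    assert tf3 == pytest.approx(np.exp(-sp.gamma * 3 * proto.length / 100.0),
                                rel=1e-12)


def test_path_transfer_function_composition(chain_tree):
    """TF over two consecutive segments equals the product of the two
    single-segment transfer functions."""
    grid = FrequencyGrid(f0=1.0, n_harmonics=12)
    tf_ab = path_transfer_function(chain_tree, "root_in", "b", grid)
    tf_bc = path_transfer_function(chain_tree, "b", "c", grid)
    tf_ac = path_transfer_function(chain_tree, "root_in", "c", grid)
    assert tf_ac.values == pytest.approx(tf_ab.values * tf_bc.values, rel=1e-9)


def test_path_transfer_function_off_path_rejected(ref_tree):
    grid = FrequencyGrid(f0=1.0, n_harmonics=4)
    with pytest.raises(ValueError, match="not downstream"):
        path_transfer_function(ref_tree, "carotid", "femoral", grid)


def test_brachial_transfer_function_has_low_frequency_peak(ref_tree):
    """The aorta-to-brachial TF modulus shows a resonant peak in the
    few-Hz band (pressure amplification toward the arm)."""
    grid = FrequencyGrid(f0=70 / 60.0, n_harmonics=30)
    tf = np.abs(path_transfer_function(
        ref_tree, "ascending_aorta", "brachial", grid).values)
    band = (grid.frequencies >= 2.0) & (grid.frequencies <= 8.0)
    k = np.argmax(tf[band])
    peak_f = grid.frequencies[band][k]
    # local maximum within the band, amplitude above unity
    assert tf[band][k] > 1.5
    assert 2.0 < peak_f < 8.0
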