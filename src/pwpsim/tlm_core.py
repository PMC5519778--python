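"""Frequency-domain transmission-line mathematics for the arterial tree.

Each arterial segment behaves as a lossy electrical transmission line
whose characteristic impedance Z0 and propagation constant gamma follow
from Womersley's oscillatory-flow theory:

    Z0    = rho*c0/(pi r^2) * (1-sigma^2)^(-1/2) * (1-F10)^(-1/2) * e^(+j phi/2)
    gamma = (j w / c0)      * (1-sigma^2)^(+1/2) * (1-F10)^(-1/2) * e^(-j phi/2)
    c0    = sqrt(E h / (rho D))                  (Moens-Korteweg)

with F10 = 2 J1(a j^(3/2)) / (a j^(3/2) J0(a j^(3/2))) the Womersley
function of the Womersley number a = r sqrt(w/nu).  A segment of length
l terminated by impedance ZL presents the input impedance

    Zin = Z0 * ((ZL-Z0) e^(-gl) + (ZL+Z0) e^(+gl))
              / ((Z0-ZL) e^(-gl) + (ZL+Z0) e^(+gl)),

and the tree input impedance is obtained by a leaf-to-root recursion
(Windkessel loads at the leaves, parallel combination at bifurcations).
All impedances are volumetric (pressure / volume flow) in Pa·s·m^-5;
the DC (w = 0) limit is computed on the resistive Poiseuille skeleton
because the Womersley expressions are singular there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .arterial_tree import (
    ArterialSegment,
    ArterialTree,
    HemodynamicConstants,
    WindkesselLoad,
)

__all__ = [
    "FrequencyGrid",
    "SegmentSpectralProps",
    "ComplexSpectrum",
    "TreeImpedances",
    "womersley_F10",
    "moens_korteweg_speed",
    "segment_spectral_props",
    "windkessel_impedance",
    "input_impedance",
    "combine_bifurcation",
    "reflection_coefficient",
    "segment_transfer_function",
    "poiseuille_resistance",
    "tree_dc_impedance",
    "tree_input_impedance",
    "path_transfer_function",
    "SingularLineError",
]

_CM = 1e-2  # cm -> m


class SingularLineError(ArithmeticError):
    """Denominator of a transmission-line expression vanished."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Harmonics 0..N of a fundamental f0 = HR/60.

    ``omega[k] = 2 pi k f0`` in rad/s; harmonic 0 is the DC component.
    """

    f0: float
    n_harmonics: int

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("fundamental frequency must be positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")

    @classmethod
    def for_waveform(cls, n_samples: int, fs: float) -> "FrequencyGrid":
        """Grid matching ``numpy.fft.rfft`` of a one-period signal."""
        return cls(f0=fs / n_samples, n_harmonics=n_samples // 2)

    @property
    def frequencies(self) -> np.ndarray:
        return self.f0 * np.arange(self.n_harmonics + 1)

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return self.n_harmonics + 1


@dataclass(frozen=True)
class SegmentSpectralProps:
    """Per-frequency transmission-line properties of one segment.

    ``alpha`` Womersley number, ``F10`` Womersley function, ``Z0``
    characteristic impedance (Pa·s·m^-5), ``gamma`` propagation constant
    (1/m), ``c0`` Moens-Korteweg speed (m/s).
    """

    alpha: np.ndarray
    F10: np.ndarray
    Z0: np.ndarray
    gamma: np.ndarray
    c0: float


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex values on a frequency grid with a role tag."""

    grid: FrequencyGrid
    values: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.grid):
            raise ValueError("spectrum length does not match its grid")


def womersley_F10(alpha):
    """Womersley's F10(alpha) = 2 J1(z)/(z J0(z)) with z = alpha j^(3/2).

    Evaluated with exponentially scaled complex Bessel functions, which
    keeps the ratio finite for arbitrarily large alpha (the common
    scaling factor cancels).  F10 -> 1 as alpha -> 0 and -> 0 as
    alpha -> infinity.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("Womersley number must be non-negative")
    z = alpha * np.exp(0.75j * np.pi)
    out = np.ones_like(z)
    nz = alpha > 1e-8
    zz = z[nz] if z.ndim else z
    if np.any(nz):
        ratio = special.jve(1, zz) / special.jve(0, zz)
        if z.ndim:
            out[nz] = 2.0 * ratio / zz
        else:
            out = 2.0 * ratio / zz
    return out if out.ndim else complex(out)


def moens_korteweg_speed(seg: ArterialSegment, const: HemodynamicConstants) -> float:
    """c0 = sqrt(E h / (rho D)) in m/s (geometry given in cm)."""
    return math.sqrt(
        seg.young_modulus * (seg.thickness * _CM)
        / (const.rho_si * seg.diameter * _CM)
    )


def segment_spectral_props(
    seg: ArterialSegment,
    omega,
    const: HemodynamicConstants = HemodynamicConstants(),
) -> SegmentSpectralProps:
    """Evaluate alpha, F10, Z0 and gamma for one segment at ``omega`` > 0.

    Note the opposite signs of the (1 - sigma^2) exponents in Z0 versus
    gamma and of the viscoelastic phase e^(±j phi/2).  DC is refused:
    the w = 0 limit lives on the resistive skeleton
    (:func:`tree_dc_impedance`).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive; DC is handled separately")
    r_m = seg.radius * _CM
    c0 = moens_korteweg_speed(seg, const)
    alpha = r_m * np.sqrt(omega / const.nu_si)
    F10 = np.atleast_1d(womersley_F10(alpha))
    phi = np.asarray([const.phi_at(w) for w in np.atleast_1d(omega)])
    s_fac = 1.0 - const.sigma**2
    visc = (1.0 - F10) ** -0.5
    Z0 = (const.rho_si * c0 / (math.pi * r_m**2)) \
        * s_fac**-0.5 * visc * np.exp(0.5j * phi)
    gamma = (1j * omega / c0) * s_fac**0.5 * visc * np.exp(-0.5j * phi)
    if omega.ndim == 0:
        return SegmentSpectralProps(
            float(alpha), complex(F10[0]), complex(Z0[0]), complex(gamma[0]), c0
        )
    return SegmentSpectralProps(alpha, F10, Z0, gamma, c0)


def windkessel_impedance(load: WindkesselLoad, omega) -> complex | np.ndarray:
    """Z(w) = R1 + R0 / (1 + j w R0 Cp): R1 + R0 at DC, R1 at high w."""
    omega = np.asarray(omega, dtype=float)
    z = load.R1 + load.R0 / (1.0 + 1j * omega * load.R0 * load.Cp)
    return complex(z) if z.ndim == 0 else z


def input_impedance(Z0, gamma, length_cm: float, ZL):
    """Input impedance of a line of length l (cm) terminated by ZL.

    Implements the exponential-form line equation; a matched load
    (ZL = Z0) returns Z0 and a zero-length line returns ZL.
    """
    gl = np.asarray(gamma) * (length_cm * _CM)
    ep, em = np.exp(gl), np.exp(-gl)
    num = (ZL - Z0) * em + (ZL + Z0) * ep
    den = (Z0 - ZL) * em + (ZL + Z0) * ep
    if np.any(np.abs(den) == 0):
        raise SingularLineError("vanishing denominator in line input impedance")
    z = Z0 * num / den
    return complex(z) if np.asarray(z).ndim == 0 else z


def combine_bifurcation(Z1, Z2=None):
    """Terminal impedance seen by a mother segment.

    Two daughters combine in parallel, Z1 Z2/(Z1+Z2); with a single
    daughter the terminal impedance is the daughter's input impedance
    unchanged.
    """
    if Z2 is None:
        return Z1
    den = Z1 + Z2
    if np.any(np.abs(den) == 0):
        raise SingularLineError("Z1 + Z2 = 0 at a bifurcation")
    return Z1 * Z2 / den


def reflection_coefficient(ZL, Z0):
    """Gamma = (ZL - Z0)/(ZL + Z0); 0 when matched, -> 1 for a closed end."""
    den = ZL + Z0
    if np.any(np.abs(den) == 0):
        raise SingularLineError("ZL + Z0 = 0 in reflection coefficient")
    return (ZL - Z0) / den


def segment_transfer_function(gamma, length_cm: float, Gamma, as_printed: bool = False):
    """Distal/proximal pressure ratio of a terminated line segment.

    Canonical terminated-line form ``(1 + G) / (e^(gl) + G e^(-gl))``:
    a matched segment (G = 0) is the pure propagation factor e^(-gl)
    and a zero-length segment is the identity.  ``as_printed`` selects
    the simplified variant ``(1 + G) / (e^(gl) + e^(-gl))`` that drops
    the reflection weight from the backward term, kept for comparison.
    """
    gl = np.asarray(gamma) * (length_cm * _CM)
    if as_printed:
        den = np.exp(gl) + np.exp(-gl)
    else:
        den = np.exp(gl) + Gamma * np.exp(-gl)
    if np.any(np.abs(den) == 0):
        raise SingularLineError("vanishing denominator in transfer function")
    tf = (1.0 + Gamma) / den
    return complex(tf) if np.asarray(tf).ndim == 0 else tf


# -- DC (Poiseuille) skeleton ---------------------------------------------

def poiseuille_resistance(seg: ArterialSegment, const: HemodynamicConstants) -> float:
    """Steady-flow resistance 8 mu l / (pi r^4) in Pa·s·m^-5."""
    mu = const.rho_si * const.nu_si  # dynamic viscosity, Pa·s
    return 8.0 * mu * (seg.length * _CM) / (math.pi * (seg.radius * _CM) ** 4)


def tree_dc_impedance(
    tree: ArterialTree,
    const: HemodynamicConstants = HemodynamicConstants(),
    _results: dict[int, tuple[float, float]] | None = None,
) -> float:
    """DC input resistance of the tree on its resistive skeleton.

    Per-segment Poiseuille resistance in series, terminal R1 + R0 at the
    leaves, parallel combination at bifurcations.  This is the total
    peripheral resistance seen by the heart.
    """
    zl: dict[int, float] = {}
    zin: dict[int, float] = {}
    for seg_id in tree.postorder():
        seg = tree.segments[seg_id]
        if seg.terminal_load is not None:
            load_dc = seg.terminal_load.R1 + seg.terminal_load.R0
        elif len(seg.children) == 1:
            load_dc = zin[seg.children[0]]
        else:
            a, b = (zin[c] for c in seg.children)
            load_dc = a * b / (a + b)
        zl[seg_id] = load_dc
        zin[seg_id] = poiseuille_resistance(seg, const) + load_dc
    if _results is not None:
        for i in zin:
            _results[i] = (zin[i], zl[i])
    return zin[tree.root]


@dataclass(frozen=True)
class TreeImpedances:
    """Per-segment input/terminal impedances over a frequency grid.

    ``z_input[i][k]`` is the impedance looking downstream at the
    proximal end of segment i at harmonic k; ``z_load[i][k]`` the
    impedance terminating segment i at its distal end.  Harmonic 0 is
    the DC (Poiseuille) value.  ``props[i]`` holds Z0/gamma/c0 for the
    positive harmonics.
    """

    grid: FrequencyGrid
    z_input: dict[int, np.ndarray]
    z_load: dict[int, np.ndarray]
    props: dict[int, SegmentSpectralProps]
    root: int

    @property
    def root_impedance(self) -> ComplexSpectrum:
        return ComplexSpectrum(self.grid, self.z_input[self.root], "impedance")


def tree_input_impedance(
    tree: ArterialTree,
    grid: FrequencyGrid,
    const: HemodynamicConstants = HemodynamicConstants(),
) -> TreeImpedances:
    """Recursive (leaf-to-root) input impedance of the whole tree.

    For every positive harmonic the Windkessel loads are propagated up
    through the line equation, combining in parallel at bifurcations;
    harmonic 0 is filled from the resistive DC skeleton.  Per-segment
    entry impedances are retained for transfer-function assembly and
    local flow computation.
    """
    omega = grid.omega[1:]
    n = len(grid)
    props: dict[int, SegmentSpectralProps] = {}
    z_input: dict[int, np.ndarray] = {}
    z_load: dict[int, np.ndarray] = {}
    dc: dict[int, tuple[float, float]] = {}
    tree_dc_impedance(tree, const, _results=dc)
    for seg_id in tree.postorder():
        seg = tree.segments[seg_id]
        sp = segment_spectral_props(seg, omega, const)
        props[seg_id] = sp
        if seg.terminal_load is not None:
            zl = windkessel_impedance(seg.terminal_load, omega)
        elif len(seg.children) == 1:
            zl = z_input[seg.children[0]][1:]
        else:
            zl = combine_bifurcation(*(z_input[c][1:] for c in seg.children))
        try:
            zi = input_impedance(sp.Z0, sp.gamma, seg.length, zl)
        except SingularLineError as err:
            raise SingularLineError(f"segment {seg_id}: {err}") from None
        z_load[seg_id] = np.concatenate(([dc[seg_id][1]], zl))
        z_input[seg_id] = np.concatenate(([dc[seg_id][0]], zi))
        assert len(z_input[seg_id]) == n
    return TreeImpedances(grid, z_input, z_load, props, tree.root)


def _partial_props(seg, frac, imped, seg_id):
    """Z at a fractional position: the distal part of the segment seen
    as a shorter line terminated by the segment's own load."""
    sp = imped.props[seg_id]
    rest = (1.0 - frac) * seg.length
    zl = imped.z_load[seg_id][1:]
    if rest == 0.0:
        return zl
    return input_impedance(sp.Z0, sp.gamma, rest, zl)


def path_transfer_function(
    tree: ArterialTree,
    from_site: str,
    to_site: str,
    grid: FrequencyGrid,
    const: HemodynamicConstants = HemodynamicConstants(),
    imped: TreeImpedances | None = None,
    as_printed: bool = False,
) -> ComplexSpectrum:
    """Pressure transfer function between two sites, proximal to distal.

    The overall TF is the product of per-segment transfer functions
    along the path, each segment's reflection coefficient taken from its
    own downstream terminal impedance.  Harmonic 0 carries the DC
    (resistive voltage-divider) ratio so that mean pressures follow the
    Poiseuille gradient.
    """
    if imped is None:
        imped = tree_input_impedance(tree, grid, const)
    seg_a, pos_a = tree.resolve_site(from_site)
    seg_b, pos_b = tree.resolve_site(to_site)
    path_a = tree.path_from_root(seg_a)
    path_b = tree.path_from_root(seg_b)
    if seg_a not in path_b:
        raise ValueError(
            f"site {to_site!r} is not downstream of site {from_site!r}"
        )
    segs = path_b[path_b.index(seg_a):]
    tf = np.ones(len(grid) - 1, dtype=complex)
    tf_dc = 1.0
    dc: dict[int, tuple[float, float]] = {}
    tree_dc_impedance(tree, const, _results=dc)
    for k, seg_id in enumerate(segs):
        seg = tree.segments[seg_id]
        sp = imped.props[seg_id]
        start = pos_a if seg_id == seg_a else 0.0
        end = pos_b if seg_id == seg_b else 1.0
        sub_len = (end - start) * seg.length
        if sub_len < 0:
            raise ValueError(
                f"site {to_site!r} lies proximal to site {from_site!r} "
                f"on segment {seg_id}"
            )
        if sub_len == 0.0:
            continue
        # impedance terminating the sub-line at its distal end
        if end == 1.0:
            zl = imped.z_load[seg_id][1:]
            zl_dc = dc[seg_id][1]
        else:
            zl = _partial_props(seg, end, imped, seg_id)
            rest = poiseuille_resistance(seg, const) * (1.0 - end)
            zl_dc = rest + dc[seg_id][1]
        Gam = reflection_coefficient(zl, sp.Z0)
        tf *= segment_transfer_function(sp.gamma, sub_len, Gam, as_printed)
        r_sub = poiseuille_resistance(seg, const) * (end - start)
        tf_dc *= zl_dc / (r_sub + zl_dc)
    return ComplexSpectrum(grid, np.concatenate(([tf_dc], tf)), "transfer-function")


def spectrum_frame(spec: ComplexSpectrum):
    """Tabulate a spectrum as (frequency_hz, real, imag, modulus, phase_deg)."""
    import pandas as pd

    v = spec.values
    return pd.DataFrame({
        "frequency_hz": spec.grid.frequencies,
        "real": v.real,
        "imag": v.imag,
        "modulus": np.abs(v),
        "phase_deg": np.degrees(np.angle(v)),
    })
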