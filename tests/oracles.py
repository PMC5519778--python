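"""Independent reference implementations used only by the tests.

These deliberately re-derive the transmission-line quantities as flat,
script-style code (power series for the Bessel functions, explicit
recursion for the tree impedance) so the package implementation is
checked against an independent route, not against itself.
"""

from math import factorial, pi, sqrt

import numpy as np

RHO_SI = 1050.0     # kg/m^3
NU_SI = 0.0381e-4   # m^2/s
SIGMA = 0.5


def bessel_j_series(n: int, z: complex, terms: int = 60) -> complex:
    """J_n(z) by its power series (adequate for |z| up to ~25)."""
    total = 0.0 + 0.0j
    for m in range(terms):
        total += (-1) ** m * (z / 2.0) ** (2 * m + n) / (
            factorial(m) * factorial(m + n)
        )
    return total


def womersley_f10_series(alpha: float) -> complex:
    z = alpha * np.exp(0.75j * np.pi)
    return 2.0 * bessel_j_series(1, z) / (z * bessel_j_series(0, z))


def segment_z0_gamma(seg, omega: float):
    """Characteristic impedance and propagation constant, re-derived."""
    r = seg.radius / 100.0
    h = seg.thickness / 100.0
    c0 = sqrt(seg.young_modulus * h / (RHO_SI * 2.0 * r))
    alpha = r * sqrt(omega / NU_SI)
    f10 = womersley_f10_series(alpha)
    z0 = (RHO_SI * c0 / (pi * r * r)) * (1 - SIGMA**2) ** -0.5 \
        * (1 - f10) ** -0.5
    gamma = (1j * omega / c0) * (1 - SIGMA**2) ** 0.5 * (1 - f10) ** -0.5
    return z0, gamma


def flat_tree_impedance(tree, omega: float) -> complex:
    """Post-order input impedance of a whole tree, written as a direct
    recursive script over the topology."""

    def z_input(seg_id: int) -> complex:
        seg = tree.segments[seg_id]
        if seg.terminal_load is not None:
            wk = seg.terminal_load
            zl = wk.R1 + wk.R0 / (1.0 + 1j * omega * wk.R0 * wk.Cp)
        elif len(seg.children) == 1:
            zl = z_input(seg.children[0])
        else:
            za, zb = (z_input(c) for c in seg.children)
            zl = za * zb / (za + zb)
        z0, gamma = segment_z0_gamma(seg, omega)
        gl = gamma * seg.length / 100.0
        num = (zl - z0) * np.exp(-gl) + (zl + z0) * np.exp(gl)
        den = (z0 - zl) * np.exp(-gl) + (zl + z0) * np.exp(gl)
        return z0 * num / den

    return z_input(tree.root)
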