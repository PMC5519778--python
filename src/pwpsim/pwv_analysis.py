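"""Pulse-wave feature extraction: foot timing, PWV, ABI and wave separation.

Two timing methods are implemented for the pulse foot — the
intersecting-tangent method (intersection of the maximum-upstroke
tangent with the horizontal through the preceding diastolic minimum)
and the maximum-slope method (time of peak dP/dt) — plus the
theoretical Moens-Korteweg route in which each segment contributes a
transit time length/c0.  Both timing methods use parabolic sub-sample
refinement of the derivative peak so that results do not hinge on the
sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arterial_tree import ArterialTree, HemodynamicConstants
from .tlm_core import moens_korteweg_speed
from .wave_synthesis import MMHG, ML, PressureWaveform, SiteWaveforms
from .cardiac_source import FlowWaveform

__all__ = [
    "FootTimes",
    "PWVResult",
    "WSAResult",
    "detect_foot",
    "foot_intersecting_tangent",
    "foot_max_slope",
    "transit_time",
    "compute_pwv",
    "theoretical_pwv",
    "abi",
    "estimate_characteristic_impedance",
    "wave_separation",
    "analyze_simulation",
]


@dataclass(frozen=True)
class FootTimes:
    """Foot timing of one pressure waveform (seconds within the period).

    ``tangent`` is the intersecting-tangent foot, ``max_slope`` the time
    of peak dP/dt (the tangent foot never follows it); ``slope`` the
    peak derivative (mmHg/s) and ``diastolic_min`` the preceding
    diastolic minimum value (mmHg).
    """

    tangent: float
    max_slope: float
    slope: float
    diastolic_min: float


def _cyclic_derivative(p: np.ndarray, fs: float) -> np.ndarray:
    return (np.roll(p, -1) - np.roll(p, 1)) * fs / 2.0


def _parabolic_peak(y: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-sample offset and refined value of a discrete extremum."""
    ym, y0, yp = y[(k - 1) % len(y)], y[k], y[(k + 1) % len(y)]
    denom = ym - 2.0 * y0 + yp
    if denom == 0.0:
        return 0.0, y0
    delta = 0.5 * (ym - yp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return delta, y0 - 0.25 * (ym - yp) * delta


def detect_foot(p: PressureWaveform, search_fraction: float = 0.5) -> FootTimes:
    """Locate the systolic foot of a periodic pressure waveform.

    The derivative peak (central differences, cyclic, earliest wins on
    ties) fixes the maximum-slope time; the diastolic minimum is the
    waveform minimum within the ``search_fraction`` of the period that
    precedes it; the tangent foot is where the upstroke tangent meets
    the horizontal through that minimum.
    """
    y = np.asarray(p.samples, dtype=float)
    n = len(y)
    d = _cyclic_derivative(y, p.fs)
    k = int(np.argmax(d))
    delta, slope = _parabolic_peak(d, k)
    if slope <= 0.0:
        raise ValueError("no systolic upstroke found (flat waveform)")
    t_up = (k + delta) / p.fs
    p_up = float(np.interp(k + delta, np.arange(n + 1), np.append(y, y[0])))
    # diastolic minimum in the window preceding the upstroke (cyclic)
    w = max(2, int(round(search_fraction * n)))
    # the sub-sample correction to a quadratic minimum's *value* is
    # second order in 1/fs, so the raw sample minimum suffices here
    idx = (np.arange(k - w, k + 1)) % n
    p_min = float(np.min(y[idx]))
    t_foot = t_up - (p_up - p_min) / slope
    return FootTimes(tangent=t_foot, max_slope=t_up, slope=slope,
                     diastolic_min=p_min)


def foot_intersecting_tangent(p: PressureWaveform) -> float:
    """Foot time by the intersecting-tangent method (seconds)."""
    return detect_foot(p).tangent


def foot_max_slope(p: PressureWaveform) -> float:
    """Foot time by the maximum-slope method (seconds)."""
    return detect_foot(p).max_slope


def transit_time(t_proximal: float, t_distal: float, period: float) -> float:
    """Foot-to-foot delay wrapped into [0, period)."""
    return (t_distal - t_proximal) % period


def compute_pwv(
    foot_proximal: FootTimes,
    foot_distal: FootTimes,
    length_cm: float,
    method: str = "tan",
    period: float | None = None,
) -> float:
    """PWV = path length / transit time, in m/s.

    ``method`` selects the timing ("tan" or "max").  When ``period`` is
    given, the delay is wrapped into one cardiac period; a delay beyond
    three quarters of the period is rejected as mis-ordered feet.
    """
    attr = {"tan": "tangent", "max": "max_slope"}[method]
    dt = getattr(foot_distal, attr) - getattr(foot_proximal, attr)
    if period is not None:
        dt %= period
        if dt > 0.75 * period:
            raise ValueError(
                f"transit time {dt:.3f}s wraps beyond 3/4 period; "
                "feet are mis-ordered"
            )
    if dt <= 0:
        raise ValueError("non-positive transit time")
    return (length_cm / 100.0) / dt


def theoretical_pwv(
    tree: ArterialTree,
    site_a: str,
    site_b: str,
    const: HemodynamicConstants = HemodynamicConstants(),
) -> float:
    """Moens-Korteweg path PWV between two sites (m/s).

    Each segment contributes a transit time length/c0; length and time
    are accumulated root-to-site and differenced between the two sites
    (the same subtraction convention as the measured path length), so
    the result is the harmonic-type mean speed over the non-shared part
    of the paths.
    """
    def accumulate(site: str) -> tuple[float, float]:
        seg_id, pos = tree.resolve_site(site)
        length = time = 0.0
        for i in tree.path_from_root(seg_id):
            seg = tree.segments[i]
            frac = pos if i == seg_id else 1.0
            l_m = frac * seg.length / 100.0
            length += l_m
            time += l_m / moens_korteweg_speed(seg, const)
        return length, time

    la, ta = accumulate(site_a)
    lb, tb = accumulate(site_b)
    return (lb - la) / (tb - ta)


def abi(tibial_p: PressureWaveform, brachial_p: PressureWaveform) -> float:
    """Ankle-brachial index: tibial SBP / brachial SBP."""
    return tibial_p.systolic / brachial_p.systolic


def estimate_characteristic_impedance(
    z_root: np.ndarray, band: tuple[int, int] = (4, 10)
) -> float:
    """Aortic characteristic impedance as the mean input-impedance
    modulus over a mid-frequency harmonic band (default 4-10), where
    reflections largely cancel."""
    lo, hi = band
    zc = float(np.mean(np.abs(z_root[lo:hi + 1])))
    if zc <= 0:
        raise ValueError("non-positive characteristic impedance estimate")
    return zc


@dataclass(frozen=True)
class WSAResult:
    """Wave separation of a site's pressure into forward and backward
    components, with reflected-wave timing.

    ``pf``/``pb`` in mmHg (the mean pressure is assigned to the forward
    wave); ``rwtt`` reflected-wave transit time in seconds (None when
    the backward wave is negligible); ``erd_cm`` effective reflection
    distance PWV * RWTT / 2.
    """

    pf: PressureWaveform
    pb: PressureWaveform
    zc: float
    rwtt: float | None
    erd_cm: float | None
    reflection_negligible: bool


def wave_separation(
    p: PressureWaveform,
    q: FlowWaveform,
    zc: float,
    pwv: float | None = None,
) -> WSAResult:
    """Linear wave separation P = Pf + Pb using measured flow.

    Pf = (dP + Zc dQ)/2 + mean(P), Pb = (dP - Zc dQ)/2, with dP, dQ the
    mean-removed pressure (Pa) and flow (m^3/s) and Zc in Pa·s·m^-5.
    The reflected-wave transit time is the tangent-foot delay of Pb
    behind Pf; the effective reflection distance assumes the reflected
    wave travelled to a single equivalent site and back at ``pwv``.
    """
    if zc <= 0:
        raise ValueError("characteristic impedance must be positive")
    dp = (p.samples - np.mean(p.samples)) * MMHG
    dq = (q.samples - np.mean(q.samples)) * ML
    pf = (dp + zc * dq) / 2.0
    pb = (dp - zc * dq) / 2.0
    pf_w = PressureWaveform(pf / MMHG + np.mean(p.samples), p.period, p.fs)
    pb_w = PressureWaveform(pb / MMHG, p.period, p.fs)
    negligible = np.ptp(pb) < 1e-4 * np.ptp(dp) or np.ptp(dp) == 0.0
    rwtt = erd = None
    if not negligible:
        rwtt = transit_time(
            detect_foot(pf_w).tangent, detect_foot(pb_w).tangent, p.period
        )
        if pwv is not None:
            erd = pwv * rwtt / 2.0 * 100.0
    return WSAResult(pf_w, pb_w, zc, rwtt, erd, negligible)


@dataclass(frozen=True)
class PWVResult:
    """All PWV variants of one simulation (m/s), plus ABI and bookkeeping."""

    cfpwv_tan: float
    cfpwv_max: float
    cfpwv_c0: float
    bapwv_tan: float
    bapwv_max: float
    bapwv_c0: float
    cf_length_cm: float
    ba_length_cm: float
    cf_transit_tan: float
    ba_transit_tan: float
    abi: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def analyze_simulation(
    tree: ArterialTree,
    sim: SiteWaveforms,
    const: HemodynamicConstants = HemodynamicConstants(),
) -> PWVResult:
    """Extract cfPWV, baPWV (tangent, max-slope, Moens-Korteweg) and ABI
    from a synthesized simulation on the standard sites."""
    from .arterial_tree import path_length

    feet = {s: detect_foot(sim.pressure[s])
            for s in ("carotid", "femoral", "brachial", "tibial")}
    cf_len = path_length(tree, "carotid", "femoral")
    ba_len = path_length(tree, "brachial", "tibial")
    period = sim.period
    cf_tan = compute_pwv(feet["carotid"], feet["femoral"], cf_len, "tan", period)
    cf_max = compute_pwv(feet["carotid"], feet["femoral"], cf_len, "max", period)
    ba_tan = compute_pwv(feet["brachial"], feet["tibial"], ba_len, "tan", period)
    ba_max = compute_pwv(feet["brachial"], feet["tibial"], ba_len, "max", period)
    return PWVResult(
        cfpwv_tan=cf_tan,
        cfpwv_max=cf_max,
        cfpwv_c0=theoretical_pwv(tree, "carotid", "femoral", const),
        bapwv_tan=ba_tan,
        bapwv_max=ba_max,
        bapwv_c0=theoretical_pwv(tree, "brachial", "tibial", const),
        cf_length_cm=cf_len,
        ba_length_cm=ba_len,
        cf_transit_tan=transit_time(feet["carotid"].tangent,
                                    feet["femoral"].tangent, period),
        ba_transit_tan=transit_time(feet["brachial"].tangent,
                                    feet["tibial"].tangent, period),
        abi=abi(sim.pressure["tibial"], sim.pressure["brachial"]),
    )
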