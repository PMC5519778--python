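"""Spectral solution pipeline: flow in, pressures and flows out.

One cardiac period of aortic inflow Q1(t) is Fourier-transformed to
Q1(w); the root pressure spectrum is P1(w) = Zin(w) * Q1(w); pressure
anywhere follows by multiplying with the root-to-site transfer function
and inverting the transform.  The arterial tree is treated as linear
and time-invariant, so the steady-state periodic solution is exact
harmonic-by-harmonic (superposition) and no transient settling is
required.

Pressures are reported in mmHg (1 mmHg = 133.322 Pa); flows in ml/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arterial_tree import ArterialTree, HemodynamicConstants
from .cardiac_source import FlowWaveform
from .tlm_core import (
    ComplexSpectrum,
    FrequencyGrid,
    TreeImpedances,
    path_transfer_function,
    tree_input_impedance,
)

__all__ = ["PressureWaveform", "SiteWaveforms", "synthesize", "site_flow"]

MMHG = 133.322  # Pa per mmHg
ML = 1e-6       # m^3 per ml


@dataclass(frozen=True)
class PressureWaveform:
    """One period of pressure at a site, uniformly sampled, in mmHg."""

    samples: np.ndarray
    period: float
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    @property
    def systolic(self) -> float:
        return float(np.max(self.samples))

    @property
    def diastolic(self) -> float:
        return float(np.min(self.samples))

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))


@dataclass
class SiteWaveforms:
    """Synthesized pressure/flow waveforms at named sites.

    ``pressure[site]`` in mmHg and ``flow[site]`` in ml/s over one
    period; ``root_pressure_spectrum`` is P1(w) in Pa (DC included) and
    ``impedances`` the per-segment spectra used to build them.
    """

    grid: FrequencyGrid
    period: float
    fs: float
    pressure: dict[str, PressureWaveform]
    flow: dict[str, FlowWaveform] = field(default_factory=dict)
    root_pressure_spectrum: ComplexSpectrum | None = None
    site_pressure_spectra: dict[str, np.ndarray] = field(default_factory=dict)
    impedances: TreeImpedances | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (site, time_s, pressure_mmHg, flow_ml_per_s)."""
        frames = []
        for site, p in self.pressure.items():
            q = self.flow.get(site)
            frames.append(pd.DataFrame({
                "site": site,
                "time_s": p.times,
                "pressure_mmHg": p.samples,
                "flow_ml_per_s": q.samples if q is not None else np.nan,
            }))
        return pd.concat(frames, ignore_index=True)


def synthesize(
    tree: ArterialTree,
    flow: FlowWaveform,
    sites: list[str] | None = None,
    const: HemodynamicConstants = HemodynamicConstants(),
    with_flows: bool = True,
) -> SiteWaveforms:
    """Run the full frequency-domain pipeline for one inflow period.

    Steps: FFT of Q1 -> P1(w) = Zin(w) Q1(w) -> P_site(w) = P1(w) *
    TF(root->site, w) -> inverse FFT.  Real output is guaranteed by the
    one-sided (conjugate-symmetric) transform; the DC harmonic runs
    through the resistive skeleton, so the root mean pressure equals
    mean flow times the DC input impedance.
    """
    if sites is None:
        sites = sorted(tree.sites)
    n = len(flow.samples)
    grid = FrequencyGrid.for_waveform(n, flow.fs)
    imped = tree_input_impedance(tree, grid, const)
    q_spec = np.fft.rfft(flow.samples * ML)           # m^3/s
    p1 = imped.z_input[tree.root] * q_spec            # Pa
    result = SiteWaveforms(
        grid=grid, period=flow.period, fs=flow.fs, pressure={},
        root_pressure_spectrum=ComplexSpectrum(grid, p1, "pressure"),
        impedances=imped,
    )
    for site in sites:
        seg_id, pos = tree.resolve_site(site)
        if seg_id == tree.root and pos == 0.0:
            p_spec = p1
        else:
            tf = path_transfer_function(
                tree, _root_site(tree), site, grid, const, imped=imped
            )
            p_spec = p1 * tf.values
        result.site_pressure_spectra[site] = p_spec
        samples = np.fft.irfft(p_spec, n) / MMHG
        result.pressure[site] = PressureWaveform(samples, flow.period, flow.fs)
        if with_flows:
            result.flow[site] = site_flow(
                tree, site, grid, p_spec, imped, flow.fs, const
            )
    return result


def _root_site(tree: ArterialTree) -> str:
    """Name of (or a synthetic handle for) the root inlet site."""
    for name, (seg_id, pos) in tree.sites.items():
        if seg_id == tree.root and pos == 0.0:
            return name
    tree.sites["_root"] = (tree.root, 0.0)
    return "_root"


def site_flow(
    tree: ArterialTree,
    site: str,
    grid: FrequencyGrid,
    p_spec: np.ndarray,
    imped: TreeImpedances,
    fs: float,
    const: HemodynamicConstants = HemodynamicConstants(),
) -> FlowWaveform:
    """Volume flow at a site: Q(w) = P(w) / Z_downstream(w).

    The local impedance looking downstream is the segment's input
    impedance at the site position (terminal impedance when the site
    sits at the distal end).
    """
    seg_id, pos = tree.resolve_site(site)
    if pos == 0.0:
        z = imped.z_input[seg_id]
    elif pos == 1.0:
        z = imped.z_load[seg_id]
    else:
        from .tlm_core import _partial_props, poiseuille_resistance, tree_dc_impedance

        dc: dict[int, tuple[float, float]] = {}
        tree_dc_impedance(tree, const, _results=dc)
        z_ac = _partial_props(tree.segments[seg_id], pos, imped, seg_id)
        z_dc = dc[seg_id][1] + poiseuille_resistance(
            tree.segments[seg_id], const) * (1.0 - pos)
        z = np.concatenate(([z_dc], z_ac))
    # the grid was built from the sample count, so f0 = fs / n exactly
    n_samples = int(round(fs / grid.f0))
    samples = np.fft.irfft(p_spec / z, n_samples) / ML
    return FlowWaveform(samples, n_samples / fs, fs)
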