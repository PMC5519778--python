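"""Parameter-sweep studies on the reference arterial tree.

Three in-silico studies probe how measured PWV responds to factors
other than the wall stiffness it is meant to index:

* **Study 1** — global Young's modulus scaling (50-150 % of default).
* **Study 2** — heart rate (60-100 bpm, LVET tied to HR by regression)
  and LVET alone (0.10-0.45 s at fixed 70 bpm).
* **Study 3** — peripheral resistance: both Windkessel resistors scaled
  together (50-150 %), load compliances held fixed; a companion
  compliance sweep scales every Cp instead.

Every grid point re-runs the full frequency-domain simulation with the
inflow mean renormalized to 70 ml/s, and reports all six PWV variants
plus ABI and mean root pressure.  The pipeline is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .arterial_tree import (
    ArterialTree,
    HemodynamicConstants,
    ScaleFactors,
    reference_tree,
    scale_tree,
)
from .cardiac_source import CardiacParameters, generate_flow, lvet_from_hr
from .pwv_analysis import PWVResult, analyze_simulation
from .wave_synthesis import SiteWaveforms, synthesize

__all__ = [
    "SweepSpec",
    "run_simulation",
    "run_sweep",
    "dependency_stats",
    "run_study",
    "STUDY_PRESETS",
]

log = logging.getLogger("pwpsim")

SWEEPABLE = ("e_scale", "hr", "lvet", "rp_scale", "cp_scale", "r0_scale")

_PWV_COLUMNS = ["cfpwv_tan", "cfpwv_max", "cfpwv_c0",
                "bapwv_tan", "bapwv_max", "bapwv_c0"]


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: which parameter moves, over which grid.

    ``parameter`` is one of e_scale | hr | lvet | rp_scale | cp_scale |
    r0_scale.  HR sweeps derive LVET from the HR regression; LVET sweeps
    hold HR at the fixed cardiac value.  ``seed`` is accepted for config
    completeness; the pipeline is deterministic.
    """

    parameter: str
    grid: tuple[float, ...]
    hr: float = 70.0
    lvet: float = 0.3
    mean_flow: float = 70.0
    fs: float = 1000.0
    shape: str = "half_sine"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        g = np.asarray(self.grid, dtype=float)
        if len(g) == 0 or (len(g) > 1 and not np.all(np.diff(g) > 0)):
            raise ValueError("grid must be non-empty and strictly increasing")


def run_simulation(
    tree: ArterialTree,
    hr: float = 70.0,
    lvet: float = 0.3,
    mean_flow: float = 70.0,
    fs: float = 1000.0,
    shape: str = "half_sine",
    const: HemodynamicConstants = HemodynamicConstants(),
) -> tuple[SiteWaveforms, PWVResult]:
    """One full simulation on the standard sites plus its PWV analysis."""
    p = CardiacParameters(hr=hr, lvet=lvet, mean_flow=mean_flow, fs=fs)
    flow = generate_flow(p, shape)
    sim = synthesize(tree, flow, const=const)
    return sim, analyze_simulation(tree, sim, const)


def run_sweep(
    spec: SweepSpec,
    tree: ArterialTree | None = None,
    const: HemodynamicConstants = HemodynamicConstants(),
) -> pd.DataFrame:
    """Execute a sweep; one row per grid point.

    Columns: the swept value, the realized HR/LVET, all six PWVs, ABI
    and mean root pressure (mmHg).
    """
    if tree is None:
        tree = reference_tree()
    rows = []
    for value in spec.grid:
        hr, lvet = spec.hr, spec.lvet
        factors = ScaleFactors()
        if spec.parameter == "hr":
            hr = value
            lvet = lvet_from_hr(hr)
        elif spec.parameter == "lvet":
            lvet = value
        else:
            factors = ScaleFactors(**{spec.parameter: value})
        point_tree = scale_tree(tree, factors)
        try:
            sim, res = run_simulation(
                point_tree, hr=hr, lvet=lvet, mean_flow=spec.mean_flow,
                fs=spec.fs, shape=spec.shape, const=const,
            )
        except Exception as err:
            raise RuntimeError(
                f"sweep {spec.parameter}={value}: simulation failed ({err})"
            ) from err
        row = {spec.parameter: value, "hr": hr, "lvet": lvet,
               **res.as_dict(),
               "mean_root_pressure_mmHg": sim.pressure["ascending_aorta"].mean}
        rows.append(row)
        log.info("sweep %s=%g done (cfPWV_tan=%.3f)",
                 spec.parameter, value, res.cfpwv_tan)
    return pd.DataFrame(rows)


def dependency_stats(
    table: pd.DataFrame,
    parameter: str,
    reporting_unit: float,
    pwv_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Correlation and per-step dependency of each PWV on the swept value.

    For each PWV column: Pearson r with the swept parameter and its
    two-sided p-value (t distribution, n-2 df), plus the dependency
    expressed as mean ± SD of the successive-difference slopes rescaled
    to ``reporting_unit`` (e.g. 5 bpm, 0.05 s, 0.1 of the default
    scale).  A constant column yields r = NaN (flagged) and 0 ± 0.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 sweep points")
    x = table[parameter].to_numpy(float)
    cols = pwv_columns or [c for c in _PWV_COLUMNS if c in table.columns]
    out = []
    for col in cols:
        y = table[col].to_numpy(float)
        slopes = np.diff(y) / np.diff(x) * reporting_unit
        if np.ptp(y) == 0.0:
            r, pval, dep_mean, dep_sd, flagged = np.nan, np.nan, 0.0, 0.0, True
        else:
            r, pval = stats.pearsonr(x, y)
            dep_mean, dep_sd = float(np.mean(slopes)), float(np.std(slopes, ddof=1))
            flagged = False
        out.append({
            "pwv": col, "r": r, "p_value": pval,
            "dependency_mean": dep_mean, "dependency_sd": dep_sd,
            "reporting_unit": reporting_unit, "constant": flagged,
        })
    return pd.DataFrame(out)


def _scale_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.5, 1.51, 0.1), 10))


STUDY_PRESETS: dict[str, dict] = {
    "1": {"sweeps": [("e_scale", _scale_grid(), 0.1)],
          "title": "Young's modulus 50-150 %"},
    "2": {"sweeps": [("hr", tuple(np.arange(60.0, 101.0, 10.0)), 5.0),
                     ("lvet", tuple(np.round(np.arange(0.10, 0.451, 0.05), 10)),
                      0.05)],
          "title": "Heart rate and LVET"},
    "3": {"sweeps": [("rp_scale", _scale_grid(), 0.1)],
          "title": "Peripheral resistance 50-150 %"},
    "cp": {"sweeps": [("cp_scale", _scale_grid(), 0.1)],
           "title": "Load compliance 50-150 %"},
}


def run_study(
    study_id: str,
    out_dir: str | Path | None = None,
    tree: ArterialTree | None = None,
    fs: float = 1000.0,
    make_figures: bool = True,
) -> dict[str, dict]:
    """Run a preset study and (optionally) write its report bundle.

    Returns ``{parameter: {"table": DataFrame, "stats": DataFrame}}``;
    when ``out_dir`` is given, sweep tables go to CSV, dependency
    summaries to JSON and PWV-vs-parameter figures to PNG.
    """
    study_id = str(study_id)
    if study_id not in STUDY_PRESETS:
        raise ValueError(f"unknown study {study_id!r}; have {sorted(STUDY_PRESETS)}")
    preset = STUDY_PRESETS[study_id]
    if tree is None:
        tree = reference_tree()
    results: dict[str, dict] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for parameter, grid, unit in preset["sweeps"]:
        log.info("study %s: sweeping %s over %d points",
                 study_id, parameter, len(grid))
        table = run_sweep(SweepSpec(parameter=parameter, grid=grid, fs=fs),
                          tree=tree)
        summary = dependency_stats(table, parameter, unit)
        results[parameter] = {"table": table, "stats": summary}
        if out is not None:
            table.to_csv(out / f"sweep_{parameter}.csv", index=False)
            summary.to_json(out / f"dependency_{parameter}.json",
                            orient="records", indent=1)
            if make_figures:
                _sweep_figure(table, parameter, preset["title"],
                              out / f"sweep_{parameter}.png")
    return results


def _sweep_figure(table: pd.DataFrame, parameter: str, title: str,
                  path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, prefix, label in zip(axes, ("cfpwv", "bapwv"),
                                 ("cfPWV", "baPWV")):
        for method, marker in (("tan", "o"), ("max", "s"), ("c0", "^")):
            ax.plot(table[parameter], table[f"{prefix}_{method}"],
                    marker=marker, ms=4, label=f"{label}$_{{{method}}}$")
        ax.set_xlabel(parameter)
        ax.set_ylabel(f"{label} (m/s)")
        ax.legend(fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
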