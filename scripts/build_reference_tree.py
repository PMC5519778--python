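"""Assemble the vendored 55-segment reference arterial tree.

Geometry (length, mean inner radius, wall thickness) follows the
classical 55-segment systemic arterial tree of the 1-D modelling
literature (Westerhof's anatomical data as tabulated by Stergiopulos
and later users; tapered vessels carry their mean radius).  Young's
moduli are grouped into three elasticity classes:

    large       4.0e5 Pa   aorta and large central arteries
    medium      8.0e5 Pa   medium muscular arteries
    peripheral 16.0e5 Pa   peripheral arteries

Terminal three-element Windkessel loads are derived rather than copied:
the total terminal resistance is distributed over the 28 terminal
branches in inverse proportion to r^3 (Murray-type flow split), the
proximal resistor R1 is matched to the terminal segment's
Moens-Korteweg characteristic impedance rho*c0/(pi r^2) to absorb
high-frequency reflections, R0 takes the remainder, and compliances
share a total of 1.0e-8 m^5/Pa in proportion to flow so every bed has
the same RC decay time (~1.6 s).  The single free total, the parallel
terminal resistance, is calibrated by bisection so the DC input
impedance of the whole tree equals the textbook total peripheral
resistance 1.6e8 Pa·s·m^-5.

Run from the repository root:  python scripts/build_reference_tree.py
"""

from __future__ import annotations

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from pwpsim.arterial_tree import (
    ArterialSegment,
    ArterialTree,
    HemodynamicConstants,
    WindkesselLoad,
    write_tree,
    load_tree,
)
from pwpsim.tlm_core import moens_korteweg_speed, tree_dc_impedance

TOTAL_DC = 1.6e8          # Pa·s·m^-5, target DC input impedance of the tree
TOTAL_CP = 1.0e-8         # m^5/Pa, summed terminal compliance
E_CLASS = {"large": 4.0e5, "medium": 8.0e5, "peripheral": 16.0e5}

# id, name, parent, length_cm, mean radius_cm, thickness_cm, class
GEOMETRY = [
    (1,  "ascending aorta",            0,  4.0, 1.455, 0.163, "large"),
    (2,  "aortic arch A",              1,  2.0, 1.120, 0.126, "large"),
    (3,  "brachiocephalic",            1,  3.4, 0.620, 0.080, "large"),
    (4,  "R. subclavian A",            3,  3.4, 0.423, 0.067, "large"),
    (5,  "R. common carotid",          3, 17.7, 0.370, 0.063, "large"),
    (6,  "R. vertebral",               4, 14.8, 0.186, 0.045, "medium"),
    (7,  "R. subclavian B (brachial)", 4, 42.2, 0.320, 0.067, "large"),
    (8,  "R. radial",                  7, 23.5, 0.158, 0.043, "peripheral"),
    (9,  "R. ulnar A",                 7,  6.7, 0.215, 0.046, "peripheral"),
    (10, "aortic arch B",              2,  3.9, 1.070, 0.115, "large"),
    (11, "L. common carotid",          2, 20.8, 0.370, 0.063, "large"),
    (12, "L. subclavian A",           10,  3.4, 0.423, 0.066, "large"),
    (13, "thoracic aorta A",          10,  5.2, 0.999, 0.110, "large"),
    (14, "L. subclavian B (brachial)",12, 42.2, 0.320, 0.067, "large"),
    (15, "L. radial",                 14, 23.5, 0.158, 0.043, "peripheral"),
    (16, "L. ulnar A",                14,  6.7, 0.215, 0.046, "peripheral"),
    (17, "intercostals",              13,  8.0, 0.175, 0.049, "medium"),
    (18, "thoracic aorta B",          13, 10.4, 0.660, 0.100, "large"),
    (19, "abdominal aorta A",         18,  5.3, 0.610, 0.090, "large"),
    (20, "celiac A",                  18,  1.0, 0.390, 0.064, "medium"),
    (21, "celiac B",                  20,  1.0, 0.200, 0.064, "medium"),
    (22, "hepatic",                   20,  6.6, 0.220, 0.049, "medium"),
    (23, "gastric",                   21,  7.1, 0.180, 0.045, "medium"),
    (24, "splenic",                   21,  6.3, 0.275, 0.054, "medium"),
    (25, "superior mesenteric",       19,  5.9, 0.435, 0.069, "medium"),
    (26, "abdominal aorta B",         19,  1.0, 0.600, 0.080, "large"),
    (27, "L. renal",                  26,  3.2, 0.260, 0.053, "medium"),
    (28, "abdominal aorta C",         26,  1.0, 0.590, 0.080, "large"),
    (29, "R. renal",                  28,  3.2, 0.260, 0.053, "medium"),
    (30, "abdominal aorta D",         28, 10.6, 0.564, 0.075, "large"),
    (31, "inferior mesenteric",       30,  5.0, 0.160, 0.043, "medium"),
    (32, "abdominal aorta E",         30,  1.0, 0.520, 0.065, "large"),
    (33, "R. common iliac",           32,  5.8, 0.390, 0.060, "large"),
    (34, "L. common iliac",           32,  5.8, 0.390, 0.060, "large"),
    (35, "L. external iliac",         34, 14.4, 0.320, 0.053, "medium"),
    (36, "L. internal iliac",         34,  5.0, 0.200, 0.040, "peripheral"),
    (37, "L. femoral",                35, 44.3, 0.225, 0.050, "medium"),
    (38, "L. deep femoral",           35, 12.6, 0.221, 0.047, "peripheral"),
    (39, "L. posterior tibial",       37, 32.1, 0.194, 0.045, "peripheral"),
    (40, "L. anterior tibial",        37, 34.3, 0.130, 0.039, "peripheral"),
    (41, "R. external iliac",         33, 14.4, 0.320, 0.053, "medium"),
    (42, "R. internal iliac",         33,  5.0, 0.200, 0.040, "peripheral"),
    (43, "R. femoral",                41, 44.3, 0.225, 0.050, "medium"),
    (44, "R. deep femoral",           41, 12.6, 0.221, 0.047, "peripheral"),
    (45, "R. posterior tibial",       43, 32.1, 0.194, 0.045, "peripheral"),
    (46, "R. anterior tibial",        43, 34.3, 0.130, 0.039, "peripheral"),
    (47, "R. ulnar B",                 9, 17.1, 0.203, 0.046, "peripheral"),
    (48, "R. interosseous",            9,  7.9, 0.091, 0.028, "peripheral"),
    (49, "L. ulnar B",                16, 17.1, 0.203, 0.046, "peripheral"),
    (50, "L. interosseous",           16,  7.9, 0.091, 0.028, "peripheral"),
    (51, "R. internal carotid",        5, 17.6, 0.200, 0.045, "peripheral"),
    (52, "R. external carotid",        5, 17.7, 0.150, 0.042, "peripheral"),
    (53, "L. internal carotid",       11, 17.6, 0.200, 0.045, "peripheral"),
    (54, "L. external carotid",       11, 17.7, 0.150, 0.042, "peripheral"),
    (55, "L. vertebral",              12, 14.8, 0.186, 0.045, "medium"),
]


def build(parallel_terminal_resistance: float) -> ArterialTree:
    const = HemodynamicConstants()
    children: dict[int, list[int]] = {}
    for seg_id, _, parent, *_ in GEOMETRY:
        if parent:
            children.setdefault(parent, []).append(seg_id)
    leaves = [row for row in GEOMETRY if row[0] not in children]
    w = {row[0]: row[4] ** 3 for row in leaves}
    w_total = sum(w.values())
    segments = []
    for seg_id, name, parent, length, radius, thickness, cls in GEOMETRY:
        load = None
        kids = tuple(children.get(seg_id, ()))
        seg = ArterialSegment(
            id=seg_id, name=name, length=length, radius=radius,
            thickness=thickness, young_modulus=E_CLASS[cls],
            children=kids, elastic_class=cls,
            terminal_load=WindkesselLoad(1, 1, 1) if not kids else None,
        )
        if not kids:
            share = w[seg_id] / w_total
            r_total = parallel_terminal_resistance / share
            c0 = moens_korteweg_speed(seg, const)
            r1 = const.rho_si * c0 / (math.pi * (radius / 100.0) ** 2)
            if r1 >= 0.4 * r_total:   # keep R0 dominant in every bed
                r1 = 0.4 * r_total
            load = WindkesselLoad(R1=r1, R0=r_total - r1, Cp=TOTAL_CP * share)
            seg = ArterialSegment(
                id=seg_id, name=name, length=length, radius=radius,
                thickness=thickness, young_modulus=E_CLASS[cls],
                children=kids, terminal_load=load, elastic_class=cls,
            )
        segments.append(seg)
    return ArterialTree(segments)


def main() -> None:
    const = HemodynamicConstants()
    lo, hi = 1e7, 1.6e8
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if tree_dc_impedance(build(mid), const) > TOTAL_DC:
            hi = mid
        else:
            lo = mid
    tree = build(0.5 * (lo + hi))
    out = Path(__file__).resolve().parents[1] / "src/pwpsim/data/arterial_tree_55.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    write_tree(tree, out)
    check = load_tree(out)
    dc = tree_dc_impedance(check, const)
    print(f"wrote {out} ({len(check)} segments, {len(check.leaves)} terminal)")
    print(f"DC input impedance: {dc:.4e} Pa·s·m^-5 (target {TOTAL_DC:.1e})")


if __name__ == "__main__":
    main()
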