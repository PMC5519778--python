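import numpy as np
import pytest

from pwpsim.arterial_tree import (
    ArterialSegment,
    ArterialTree,
    HemodynamicConstants,
    WindkesselLoad,
    reference_tree,
)


@pytest.fixture(scope="session")
def ref_tree():
    return reference_tree()


@pytest.fixture(scope="session")
def constants():
    return HemodynamicConstants()


def make_segment(seg_id, children=(), load=None, *, length=10.0, radius=0.5,
                 thickness=0.05, E=4.0e5, name=None):
    return ArterialSegment(
        id=seg_id, name=name or f"seg{seg_id}", length=length, radius=radius,
        thickness=thickness, young_modulus=E, children=tuple(children),
        terminal_load=load,
    )


WK = WindkesselLoad(R1=1.0e8, R0=8.0e8, Cp=2.0e-9)


@pytest.fixture
def single_segment_tree():
    """One vessel closed by a Windkessel load."""
    return ArterialTree(
        [make_segment(1, load=WK)],
        sites={"inlet": (1, 0.0), "outlet": (1, 1.0)},
    )


@pytest.fixture
def seven_segment_tree():
    """Two-level symmetric-topology tree: root, two daughters, four
    grand-daughter terminals (each with its own Windkessel load)."""
    segs = [
        make_segment(1, children=(2, 3), length=8.0, radius=1.0, thickness=0.1),
        make_segment(2, children=(4, 5), length=6.0, radius=0.6, thickness=0.07),
        make_segment(3, children=(6, 7), length=7.0, radius=0.7, thickness=0.08),
        make_segment(4, load=WindkesselLoad(2e8, 1.5e9, 1.2e-9),
                     length=5.0, radius=0.3, thickness=0.04, E=8e5),
        make_segment(5, load=WindkesselLoad(3e8, 2.5e9, 0.8e-9),
                     length=4.0, radius=0.25, thickness=0.035, E=8e5),
        make_segment(6, load=WindkesselLoad(2.5e8, 2.0e9, 1.0e-9),
                     length=6.0, radius=0.35, thickness=0.045, E=8e5),
        make_segment(7, load=WindkesselLoad(4e8, 3.0e9, 0.6e-9),
                     length=5.5, radius=0.28, thickness=0.04, E=8e5),
    ]
    return ArterialTree(segs)


@pytest.fixture
def chain_tree():
    """Three segments in series (lengths 10, 20, 30 cm)."""
    segs = [
        make_segment(1, children=(2,), length=10.0),
        make_segment(2, children=(3,), length=20.0, radius=0.4),
        make_segment(3, load=WK, length=30.0, radius=0.3),
    ]
    return ArterialTree(segs, sites={
        "a": (1, 1.0), "b": (2, 1.0), "c": (3, 1.0), "root_in": (1, 0.0),
    })
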