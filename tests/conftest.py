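"""Shared fixtures: tiny hand-built topologies and text-format files.

All fixture data is generated programmatically; file-based fixtures are
written into pytest tmp directories at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

from hydrashell.trajectory import (Frame, Topology, Trajectory,
                                   assign_donor_acceptor_flags)


def make_water_topology(n_waters: int = 1) -> Topology:
    names, elems, resids, resnames, mols, bonds = [], [], [], [], [], []
    for m in range(n_waters):
        b = 3 * m
        names += ["OW", "HW1", "HW2"]
        elems += ["O", "H", "H"]
        resids += [m + 1] * 3
        resnames += ["SOL"] * 3
        mols += [m] * 3
        bonds += [(b, b + 1), (b, b + 2)]
    top = Topology(np.array(names, dtype=object), np.array(elems, dtype=object),
                   np.array(resids), np.array(resnames, dtype=object),
                   np.array(mols), np.array(bonds))
    assign_donor_acceptor_flags(top)
    return top


def make_point_topology(n: int, element: str = "C") -> Topology:
    return Topology(np.array([element] * n, dtype=object),
                    np.array([element] * n, dtype=object),
                    np.arange(1, n + 1),
                    np.array(["PNT"] * n, dtype=object),
                    np.arange(n))


def make_trajectory(coords, box_edge=None, dt=1.0, topology=None) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    if topology is None:
        topology = make_point_topology(coords.shape[1])
    box = None if box_edge is None else np.diag([box_edge] * 3)
    return Trajectory(topology, coords, box, np.arange(coords.shape[0]) * dt)


@pytest.fixture
def water_topology():
    return make_water_topology(1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
CRYST1   70.000   70.000   70.000  90.00  90.00  90.00 P 1           1
ATOM      1  OW  HOH A   1      10.000  10.000  10.000  1.00  0.00           O
ATOM      2  HW1 HOH A   1      10.950  10.000  10.000  1.00  0.00           H
ATOM      3  HW2 HOH A   1       9.700  10.900  10.000  1.00  0.00           H
END
"""

MINIMAL_GRO = """\
one water
    3
    1SOL     OW    1   1.000   1.000   1.000
    1SOL    HW1    2   1.095   1.000   1.000
    1SOL    HW2    3   0.970   1.090   1.000
   7.00000   7.00000   7.00000
"""


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def water_gro(tmp_path):
    p = tmp_path / "water.gro"
    p.write_text(MINIMAL_GRO)
    return p
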