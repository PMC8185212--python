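"""Shared fixtures: toy complexes, graphs and network parameters."""

from __future__ import annotations

import numpy as np
import pytest

from gatedock import build_graph, init_params, make_native
from gatedock.interface_graph import InterfaceGraphPair


@pytest.fixture(scope="session")
def toy_native():
    """Small two-chain synthetic complex (7 + 5 residues, in contact)."""
    return make_native(7, 5, seed=3)


@pytest.fixture(scope="session")
def toy_pair(toy_native):
    return build_graph(toy_native)


@pytest.fixture(scope="session")
def default_params():
    return init_params(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def permute_pair(pair: InterfaceGraphPair, perm: np.ndarray) -> InterfaceGraphPair:
    """Reorder the nodes of a graph pair (tests only: breaks the
    receptor-first ordering contract on purpose)."""
    return InterfaceGraphPair(
        atoms=[pair.atoms[i] for i in perm],
        features=pair.features[perm],
        a1=pair.a1[np.ix_(perm, perm)],
        cross_dist=pair.cross_dist[np.ix_(perm, perm)],
        molecule_of=pair.molecule_of[perm],
        cutoff=pair.cutoff,
        edge_params=pair.edge_params,
    )


def make_pdb_text(lines: list[str]) -> str:
    return "\n".join(lines) + "\nEND\n"


def atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
              x: float, y: float, z: float, altloc: str = " ",
              element: str | None = None, record: str = "ATOM") -> str:
    elem = (element if element is not None else name[0]).rjust(2)
    fname = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {fname}{altloc}{resname:>3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {elem}")
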