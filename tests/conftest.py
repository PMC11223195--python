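"""Shared fixtures: hand-built universes and small synthetic systems."""

from __future__ import annotations

import warnings

import MDAnalysis as mda
import numpy as np
import pytest
from MDAnalysis.coordinates.memory import MemoryReader

from tdanalyze import helixgen as hg

warnings.filterwarnings("ignore", module="MDAnalysis")


def make_universe(coords, chain_of_atom, resid_of_atom, name_of_atom,
                  resname="ALA", dt=1.0) -> mda.Universe:
    """Build a universe from explicit per-atom metadata and (F, N, 3) coords."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    resnames = [resname] * n_atoms if isinstance(resname, str) else list(resname)

    res_keys, resindex = [], []
    for i in range(n_atoms):
        key = (chain_of_atom[i], resid_of_atom[i])
        if key not in res_keys:
            res_keys.append(key)
        resindex.append(res_keys.index(key))
    seg_keys = sorted({c for c, _ in res_keys})
    seg_of_res = [seg_keys.index(c) for c, _ in res_keys]

    u = mda.Universe.empty(n_atoms, n_residues=len(res_keys),
                           atom_resindex=np.array(resindex),
                           residue_segindex=np.array(seg_of_res),
                           n_segments=len(seg_keys), trajectory=True)
    u.add_TopologyAttr("name", list(name_of_atom))
    u.add_TopologyAttr("resid", [r for _, r in res_keys])
    u.add_TopologyAttr("resname", [resnames[[i for i, k in enumerate(resindex) if k == j][0]]
                                   for j in range(len(res_keys))])
    u.add_TopologyAttr("chainIDs", list(chain_of_atom))
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("elements", [n[0] for n in name_of_atom])
    u.load_new(coords.astype(np.float32), format=MemoryReader, dt=dt)
    return u


def two_chain_random_universe(rng, n_frames=10, n_res1=8, n_res2=8,
                              atoms_per_res=3, spread=6.0):
    """Random two-chain universe for brute-force oracle comparisons."""
    names_pool = ["CA", "N", "O", "CB", "HZ1"]
    chain, resid, names = [], [], []
    for c, n_res in (("C", n_res1), ("A", n_res2)):
        for r in range(1, n_res + 1):
            for a in range(atoms_per_res):
                chain.append(c)
                resid.append(r)
                names.append(names_pool[a % len(names_pool)])
    n_atoms = len(names)
    base = rng.uniform(-spread, spread, size=(n_atoms, 3))
    coords = base[None] + rng.normal(0, 1.5, size=(n_frames, n_atoms, 3))
    return make_universe(coords, chain, resid, names)


@pytest.fixture(scope="session")
def straight_assembly():
    return hg.build_assembly()


@pytest.fixture(scope="session")
def small_reference_systems():
    """The three standard systems at a reduced frame count for unit tests."""
    return hg.reference_systems(seed=11, n_frames=60)
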