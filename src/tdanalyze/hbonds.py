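"""Geometric hydrogen-bond detection and occupancy statistics.

A donor–hydrogen···acceptor triple counts as a hydrogen bond in a frame iff
the heavy-atom donor–acceptor distance is ≤ 3.0 Å (optionally the
hydrogen–acceptor distance instead) *and* the donor–hydrogen–acceptor angle
is ≥ 150°.  Occupancy is the percentage of frames satisfying both criteria;
for donors with several hydrogens (lysine NZ) a frame counts if *any*
hydrogen satisfies the angle test, matching the convention of published
per-(donor-atom, acceptor-atom) occupancy tables.

Aggregate pair occupancies are plain sums of the per-acceptor-atom rows
(e.g. NZ–OD1 + NZ–OD2 for the K26/D16 pair) — the published convention —
with the co-occurrence-corrected union also reported, since a sum can
double-count frames in which both component bonds are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import MDAnalysis as mda
import numpy as np
import pandas as pd

from ._geom import round_half_up
from .errors import InputError, ParameterError, SelectionError

__all__ = [
    "HBondCriteria", "RegistryEntry", "default_registry", "detect_hbond",
    "hbond_frame_mask", "occupancy_table", "AggregateOccupancy",
    "aggregate_occupancy", "distance_trace", "hbond_count_series",
    "salt_bridge_occupancy", "DEFAULT_SALT_BRIDGE_CUTOFF",
]

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (3 Å / 150° by default)."""

    distance_cutoff: float = 3.0
    angle_cutoff: float = 150.0
    distance_definition: str = "donor_acceptor"

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ParameterError(f"distance_cutoff must be > 0, got {self.distance_cutoff}")
        if not 0 <= self.angle_cutoff <= 180:
            raise ParameterError(f"angle_cutoff must be in [0, 180], got {self.angle_cutoff}")
        if self.distance_definition not in ("donor_acceptor", "hydrogen_acceptor"):
            raise ParameterError(
                "distance_definition must be 'donor_acceptor' or 'hydrogen_acceptor', "
                f"got {self.distance_definition!r}")


@dataclass(frozen=True)
class RegistryEntry:
    """One donor→acceptor pairing to monitor, on one adaptor chain."""

    pair: str                    # e.g. "K26/D16"
    label: str                   # e.g. "NZ-OD1"
    donor_chain: str
    donor_resid: int
    donor_atom: str
    hydrogens: tuple[str, ...]
    acceptor_chain: str
    acceptor_resid: int
    acceptor_atom: str

    def __post_init__(self):
        if not self.hydrogens:
            raise ParameterError(f"registry entry {self.pair} {self.label} has no hydrogens")


def default_registry(adaptor_chains: tuple[str, str] = ("A", "B"),
                     donor_chain: str = "C") -> list[RegistryEntry]:
    """The five published donor→acceptor pairings, against both adaptor
    chains: K26 NZ→D16 OD1/OD2, K26 NZ→T20 OG1, W34 NE1→T20 OG1 and
    W34 NE1→T20 backbone O."""
    base = [
        ("K26/D16", "NZ-OD1", 26, "NZ", ("HZ1", "HZ2", "HZ3"), 16, "OD1"),
        ("K26/D16", "NZ-OD2", 26, "NZ", ("HZ1", "HZ2", "HZ3"), 16, "OD2"),
        ("K26/T20", "NZ-OG1", 26, "NZ", ("HZ1", "HZ2", "HZ3"), 20, "OG1"),
        ("W34/T20", "NE1-OG1", 34, "NE1", ("HE1",), 20, "OG1"),
        ("W34/T20", "NE1-O", 34, "NE1", ("HE1",), 20, "O"),
    ]
    entries = []
    for chain in adaptor_chains:
        for pair, label, dres, datom, hyds, ares, aatom in base:
            entries.append(RegistryEntry(pair, label, donor_chain, dres, datom,
                                         hyds, chain, ares, aatom))
    return entries


def detect_hbond(donor_pos: np.ndarray, hydrogen_pos: np.ndarray,
                 acceptor_pos: np.ndarray,
                 criteria: HBondCriteria | None = None) -> bool:
    """Geometric H-bond test for one frame.

    ``hydrogen_pos`` may be one position or a (k, 3) stack; the bond is
    formed if any hydrogen passes the angle test while the distance
    criterion holds.
    """
    criteria = criteria or HBondCriteria()
    d = np.asarray(donor_pos, dtype=float)
    a = np.asarray(acceptor_pos, dtype=float)
    h = np.atleast_2d(np.asarray(hydrogen_pos, dtype=float))
    if criteria.distance_definition == "donor_acceptor":
        dist_ok = np.linalg.norm(a - d) <= criteria.distance_cutoff
        if not dist_ok:
            return False
        return bool(np.any(_dha_angles(d, h, a) >= criteria.angle_cutoff))
    # hydrogen_acceptor: the distance is per hydrogen
    dists = np.linalg.norm(a - h, axis=1)
    angles = _dha_angles(d, h, a)
    return bool(np.any((dists <= criteria.distance_cutoff)
                       & (angles >= criteria.angle_cutoff)))


def _dha_angles(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Donor–hydrogen–acceptor angles (deg) for a stack of hydrogens."""
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    c = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _resolve(u: mda.Universe, chain: str, resid: int, names) -> mda.AtomGroup:
    sel = " or ".join(f"name {n}" for n in names)
    ag = u.select_atoms(f"chainID {chain} and resid {resid} and ({sel})")
    if len(ag) != len(names):
        raise SelectionError(
            f"could not resolve atoms {names} in chain {chain} resid {resid} "
            f"(found {len(ag)})")
    return ag


def hbond_frame_mask(u: mda.Universe, entry: RegistryEntry,
                     criteria: HBondCriteria | None = None,
                     window: tuple[int, int] | None = None) -> np.ndarray:
    """Boolean per-frame H-bond formation for one registry entry."""
    criteria = criteria or HBondCriteria()
    donor = _resolve(u, entry.donor_chain, entry.donor_resid, [entry.donor_atom])
    hyds = _resolve(u, entry.donor_chain, entry.donor_resid, list(entry.hydrogens))
    acceptor = _resolve(u, entry.acceptor_chain, entry.acceptor_resid, [entry.acceptor_atom])
    start, stop = _frame_window(u, window)
    mask = np.empty(stop - start + 1, dtype=bool)
    for i, _ in enumerate(u.trajectory[start:stop + 1]):
        mask[i] = detect_hbond(donor.positions[0], hyds.positions,
                               acceptor.positions[0], criteria)
    return mask


def _frame_window(u: mda.Universe, window: tuple[int, int] | None) -> tuple[int, int]:
    n = len(u.trajectory)
    if n == 0:
        raise InputError("trajectory has no frames")
    if window is None:
        return 0, n - 1
    start, stop = int(window[0]), int(window[1])
    if not (0 <= start <= stop < n):
        raise InputError(f"frame window {window} outside trajectory of {n} frames")
    return start, stop


def occupancy_table(u: mda.Universe, registry: list[RegistryEntry] | None = None,
                    criteria: HBondCriteria | None = None,
                    window: tuple[int, int] | None = None,
                    system: str | None = None) -> pd.DataFrame:
    """Occupancy percentage per registry entry and chain.

    Columns: system, pair, label, chain, occupancy (percent of window
    frames satisfying the criteria; full precision — round for reporting).
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise InputError("registry is empty")
    criteria = criteria or HBondCriteria()
    rows = []
    for entry in registry:
        mask = hbond_frame_mask(u, entry, criteria, window)
        rows.append({
            "system": system or "", "pair": entry.pair, "label": entry.label,
            "chain": entry.acceptor_chain,
            "occupancy": 100.0 * float(mask.mean()),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AggregateOccupancy:
    """Summed pair occupancy, as reported (1 decimal, half-up) and raw."""

    reported: float
    raw: float
    components: tuple[float, ...]
    may_double_count: bool   # True when the raw sum exceeds 100%


def aggregate_occupancy(table: pd.DataFrame, pair: str, chain: str,
                        system: str | None = None) -> AggregateOccupancy:
    """Sum a residue pair's per-acceptor-atom occupancies for one chain.

    This is the published aggregation (e.g. NZ–OD1 24.85% + NZ–OD2 60.35%
    → 85.2% for K26/D16); the raw sum is kept alongside the 1-decimal
    half-up rounded value.
    """
    sel = table[(table["pair"] == pair) & (table["chain"] == chain)]
    if system is not None:
        sel = sel[sel["system"] == system]
    if sel.empty:
        raise KeyError(f"no occupancy rows for pair {pair!r} chain {chain!r}"
                       + (f" system {system!r}" if system is not None else ""))
    components = tuple(float(x) for x in sel["occupancy"])
    raw = float(np.sum(components))
    return AggregateOccupancy(reported=round_half_up(raw, 1), raw=raw,
                              components=components,
                              may_double_count=raw > 100.0)


def distance_trace(u: mda.Universe, atom1: tuple[str, int, str],
                   atom2: tuple[str, int, str],
                   window: tuple[int, int] | None = None) -> np.ndarray:
    """Per-frame distance (Å) between two named atoms, e.g. K26 NZ on the
    receptor vs D16 OD1 on an adaptor chain."""
    ag1 = _resolve(u, atom1[0], atom1[1], [atom1[2]])
    ag2 = _resolve(u, atom2[0], atom2[1], [atom2[2]])
    start, stop = _frame_window(u, window)
    out = np.empty(stop - start + 1)
    for i, _ in enumerate(u.trajectory[start:stop + 1]):
        out[i] = np.linalg.norm(ag1.positions[0].astype(float)
                                - ag2.positions[0].astype(float))
    return out


def hbond_count_series(u: mda.Universe, registry: list[RegistryEntry] | None = None,
                       criteria: HBondCriteria | None = None,
                       window: tuple[int, int] | None = None
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-frame count of simultaneously formed H-bonds.

    Returns ``(total, per_label)`` where ``total[f]`` sums over registry
    entries and ``per_label`` holds one 0/1 column per
    (pair, label, chain) entry.
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise InputError("registry is empty")
    criteria = criteria or HBondCriteria()
    cols = {}
    for entry in registry:
        mask = hbond_frame_mask(u, entry, criteria, window)
        cols[f"{entry.pair}:{entry.label}:{entry.acceptor_chain}"] = mask.astype(int)
    per_label = pd.DataFrame(cols)
    total = per_label.to_numpy().sum(axis=1)
    return total, per_label


def salt_bridge_occupancy(u: mda.Universe, basic_group: mda.AtomGroup,
                          acidic_group: mda.AtomGroup,
                          cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
                          window: tuple[int, int] | None = None) -> float:
    """Percent of frames with min distance between the charged heavy-atom
    groups ≤ cutoff (4.0 Å by default, the common literature convention)."""
    if len(basic_group) == 0 or len(acidic_group) == 0:
        raise SelectionError("salt-bridge atom groups must be non-empty")
    from MDAnalysis.lib.distances import distance_array
    start, stop = _frame_window(u, window)
    hits = 0
    for _ in u.trajectory[start:stop + 1]:
        if distance_array(basic_group.positions, acidic_group.positions).min() <= cutoff:
            hits += 1
    return 100.0 * hits / (stop - start + 1)
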