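"""Residue–residue contact maps, persistence filtering and consensus merging.

Two map levels are used, mirroring the published analysis: Cα maps with an
11 Å cutoff (coarse interface picture) and all-atom maps with a 3 Å cutoff
(specific interactions, side chains and hydrogens included).  A residue pair
is "in contact" in a frame iff the minimum distance between the selected
atom sets is ≤ cutoff; its persistence is the fraction of window frames in
contact.  Persistent maps (persistence strictly > 0.5 by default) from the
six (system × adaptor chain) combinations are merged into a consensus set
retaining pairs present in at least three of the six maps, which are then
classified as hydrophobic, hydrogen-bond and/or salt-bridge interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import MDAnalysis as mda
import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import distance_array

from .errors import AlignmentError, InputError, ParameterError, SelectionError
from .topology import HYDROPHOBIC_RESIDUES, RESIDUE_CHARGE, ComplexTopology

__all__ = [
    "ContactMap", "ConsensusContactSet", "contact_map", "persistence_filter",
    "consensus_merge", "classify_interactions", "atomistic_pair_map",
    "DEFAULT_CA_CUTOFF", "DEFAULT_AA_CUTOFF", "DEFAULT_MIDDLE_REGION",
]

DEFAULT_CA_CUTOFF = 11.0
DEFAULT_AA_CUTOFF = 3.0

#: α-helical "middle region" of the bundle used for interface asymmetry
#: summaries: receptor residues 14–41, adaptor residues 6–32.
DEFAULT_MIDDLE_REGION = {"receptor": (14, 41), "adaptor": (6, 32)}

_LEVELS = {"c_alpha": "c_alpha", "ca": "c_alpha", "all_atom": "all_atom", "aa": "all_atom"}


@dataclass
class ContactMap:
    """Per-residue-pair contact persistence between one chain pair."""

    chain_pair: tuple[str, str]
    level: str
    cutoff: float
    window: tuple[int, int]
    resids1: np.ndarray
    resids2: np.ndarray
    persistence: np.ndarray  # shape (len(resids1), len(resids2)), values in [0, 1]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.persistence, index=self.resids1, columns=self.resids2)

    def region_sum(self, region1: tuple[int, int], region2: tuple[int, int]) -> float:
        """Summed persistence over an inclusive residue-range block."""
        m1 = (self.resids1 >= region1[0]) & (self.resids1 <= region1[1])
        m2 = (self.resids2 >= region2[0]) & (self.resids2 <= region2[1])
        return float(self.persistence[np.ix_(m1, m2)].sum())

    def contact_pairs(self) -> set[tuple[int, int]]:
        """Residue-number pairs with non-zero persistence."""
        ii, jj = np.nonzero(self.persistence)
        return {(int(self.resids1[i]), int(self.resids2[j])) for i, j in zip(ii, jj)}


def _atom_selection(u: mda.Universe, chain: str, level: str, heavy_only: bool):
    if level == "c_alpha":
        sel = f"chainID {chain} and name CA"
    elif heavy_only:
        sel = f"chainID {chain} and not name H*"
    else:
        sel = f"chainID {chain}"
    ag = u.select_atoms(sel)
    if len(ag) == 0:
        raise SelectionError(f"selection {sel!r} matched no atoms")
    return ag


def _frame_window(u: mda.Universe, window: tuple[int, int] | None) -> tuple[int, int]:
    n = len(u.trajectory)
    if window is None:
        return 0, n - 1
    start, stop = int(window[0]), int(window[1])
    if not (0 <= start <= stop < n):
        raise InputError(f"frame window {window} outside trajectory of {n} frames")
    return start, stop


def contact_map(u: mda.Universe, chain_pair: tuple[str, str] = ("C", "A"),
                level: str = "c_alpha", cutoff: float | None = None,
                window: tuple[int, int] | None = None,
                heavy_only: bool = False) -> ContactMap:
    """Residue-pair contact persistence between two chains.

    ``level='c_alpha'`` uses Cα atoms (default cutoff 11 Å); ``'all_atom'``
    uses every atom including hydrogens (default cutoff 3 Å), or heavy atoms
    only with ``heavy_only=True``.  ``window`` is an inclusive frame range.
    """
    level = _LEVELS.get(level)
    if level is None:
        raise ParameterError(f"level must be one of {sorted(set(_LEVELS))}")
    if chain_pair[0] == chain_pair[1]:
        raise ParameterError("chain pair must name two distinct chains")
    if cutoff is None:
        cutoff = DEFAULT_CA_CUTOFF if level == "c_alpha" else DEFAULT_AA_CUTOFF
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0, got {cutoff}")

    ag1 = _atom_selection(u, chain_pair[0], level, heavy_only)
    ag2 = _atom_selection(u, chain_pair[1], level, heavy_only)
    resids1 = np.unique(ag1.resids)
    resids2 = np.unique(ag2.resids)
    r1_index = np.searchsorted(resids1, ag1.resids)
    r2_index = np.searchsorted(resids2, ag2.resids)
    n1, n2 = len(resids1), len(resids2)
    flat = r1_index[:, None] * n2 + r2_index[None, :]

    start, stop = _frame_window(u, window)
    counts = np.zeros(n1 * n2, dtype=np.int64)
    for _ in u.trajectory[start:stop + 1]:
        d = distance_array(ag1.positions, ag2.positions)
        hit = np.bincount(flat[d <= cutoff], minlength=n1 * n2) > 0
        counts += hit
    persistence = counts.reshape(n1, n2) / float(stop - start + 1)
    return ContactMap(chain_pair=tuple(chain_pair), level=level, cutoff=float(cutoff),
                      window=(start, stop), resids1=resids1, resids2=resids2,
                      persistence=persistence)


def persistence_filter(cmap: ContactMap, threshold: float = 0.5) -> ContactMap:
    """Zero out residue pairs whose persistence is ≤ threshold.

    The inequality is strict — a pair must persist for *more* than the
    threshold fraction of frames to be retained, so persistence exactly at
    the threshold is dropped.
    """
    if not 0 <= threshold < 1:
        raise ParameterError(f"threshold must be in [0, 1), got {threshold}")
    kept = np.where(cmap.persistence > threshold, cmap.persistence, 0.0)
    return replace(cmap, persistence=kept)


@dataclass
class ConsensusContactSet:
    """Residue pairs counted across several persistent contact maps."""

    counts: pd.DataFrame        # columns: resid1, resid2, count, retained
    n_maps: int
    min_count: int

    @property
    def retained_pairs(self) -> set[tuple[int, int]]:
        r = self.counts[self.counts["retained"]]
        return set(zip(r["resid1"].astype(int), r["resid2"].astype(int)))


def consensus_merge(maps: dict, min_count: int = 3) -> ConsensusContactSet:
    """Merge persistent contact maps into a consensus contact set.

    ``maps`` maps an arbitrary key — conventionally (system, adaptor chain)
    — to a persistence-filtered :class:`ContactMap`.  A pair's count is the
    number of maps in which it survives; it is retained iff
    ``count >= min_count`` (at least half of the canonical six maps).
    All maps must share residue indexing on both chains.
    """
    if not maps:
        raise InputError("no contact maps to merge")
    items = list(maps.values())
    ref = items[0]
    for m in items[1:]:
        if (not np.array_equal(m.resids1, ref.resids1)
                or not np.array_equal(m.resids2, ref.resids2)):
            raise AlignmentError("contact maps do not share residue indexing")
    stack = np.stack([(m.persistence > 0).astype(int) for m in items])
    counts = stack.sum(axis=0)
    ii, jj = np.nonzero(counts)
    df = pd.DataFrame({
        "resid1": ref.resids1[ii].astype(int),
        "resid2": ref.resids2[jj].astype(int),
        "count": counts[ii, jj].astype(int),
    })
    df["retained"] = df["count"] >= min_count
    df = df.sort_values(["resid1", "resid2"], ignore_index=True)
    return ConsensusContactSet(counts=df, n_maps=len(items), min_count=min_count)


def classify_interactions(consensus: ConsensusContactSet, topology: ComplexTopology,
                          occupancies: pd.DataFrame | None = None,
                          receptor_chain: str | None = None) -> pd.DataFrame:
    """Assign interaction classes to each retained consensus pair.

    A pair may carry several classes (K26/D16 is both salt bridge and
    hydrogen bond): ``hydrophobic`` iff both residues are in the
    hydrophobic set; ``salt_bridge`` iff the residues are oppositely
    charged; ``hydrogen_bond`` iff an occupancy-table row covers the pair
    with occupancy > 0.  Pairs satisfying no rule are flagged unclassified.
    """
    if consensus.counts.empty or not consensus.retained_pairs:
        raise InputError("consensus set has no retained pairs to classify")
    receptor = receptor_chain or topology.receptor.chain_id
    rows = []
    for resid1, resid2 in sorted(consensus.retained_pairs):
        l1 = topology.letter(receptor, resid1)
        l2 = topology.adaptor_chains[0].letter(resid2)
        classes = []
        if l1 in HYDROPHOBIC_RESIDUES and l2 in HYDROPHOBIC_RESIDUES:
            classes.append("hydrophobic")
        if RESIDUE_CHARGE.get(l1, 0) * RESIDUE_CHARGE.get(l2, 0) < 0:
            classes.append("salt_bridge")
        if occupancies is not None and len(occupancies):
            pair_label = f"{l1}{resid1}/{l2}{resid2}"
            sel = occupancies[(occupancies["pair"] == pair_label)
                              & (occupancies["occupancy"] > 0)]
            if len(sel):
                classes.append("hydrogen_bond")
        rows.append({
            "resid1": int(resid1), "resid2": int(resid2),
            "pair": f"{l1}{resid1}/{l2}{resid2}",
            "classes": tuple(classes),
            "unclassified": not classes,
        })
    return pd.DataFrame(rows)


def atomistic_pair_map(u: mda.Universe, residue1: tuple[str, int],
                       residue2: tuple[str, int], cutoff: float = DEFAULT_AA_CUTOFF,
                       window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Atom-pair contact persistence for one residue pair.

    Rows are atoms of ``residue1 = (chain, resid)``, columns atoms of
    ``residue2``; values are the fraction of window frames with the atom
    pair within ``cutoff``.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0, got {cutoff}")
    ags = []
    for chain, resid in (residue1, residue2):
        ag = u.select_atoms(f"chainID {chain} and resid {resid}")
        if len(ag) == 0:
            raise SelectionError(f"no atoms for chain {chain} resid {resid}")
        ags.append(ag)
    ag1, ag2 = ags
    start, stop = _frame_window(u, window)
    counts = np.zeros((len(ag1), len(ag2)), dtype=np.int64)
    for _ in u.trajectory[start:stop + 1]:
        counts += distance_array(ag1.positions, ag2.positions) <= cutoff
    persistence = counts / float(stop - start + 1)
    return pd.DataFrame(persistence, index=list(ag1.names), columns=list(ag2.names))
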