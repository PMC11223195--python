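"""Synthetic helix-bundle and trajectory generator with known ground truth.

This module builds ideal α-helices, bends them by a programmed kink,
decorates them with the named side-chain donor/acceptor atoms used in
TREM2/DAP12 interface analysis (NZ/HZ1-3 on lysine, OD1/OD2 on aspartate,
OG1 on threonine, NE1/HE1 on tryptophan, plus backbone O), and emits
multi-frame trajectories in which hydrogen-bond geometry is satisfied on a
frame-by-frame schedule.  Because every geometric quantity (kink angle,
contact pattern, H-bond occupancy) is set by construction, the analysis
modules can be validated against exact ground truth instead of against
irreproducible production MD output.

Geometry conventions
--------------------
* Ideal helix: Cα(i) = (r·cos(k·τ), r·sin(k·τ), k·d) with k = i − 1,
  rise d = 1.5 Å, radius r = 2.3 Å and twist τ = 100°/residue by default.
* A kink rotates all residues *beyond* the hinge rigidly about an axis
  through the hinge Cα, perpendicular to the local helix axis, at a chosen
  azimuth; the rotation angle is the exact segment-axis ground truth.
* Scheduled H-bonds place the acceptor atom along a donor-hydrogen
  direction at ON_DISTANCE (2.8 Å) when the frame is "on" and OFF_DISTANCE
  (5.0 Å) when "off"; both the donor–acceptor and hydrogen–acceptor 3 Å
  criteria are therefore satisfied/violated identically, with ≥ 160°
  donor–hydrogen–acceptor angles on "on" frames.
* Thermal noise is isotropic Gaussian per atom per frame and is *not*
  applied to atoms involved in a schedule, so schedules stay exactly true.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import MDAnalysis as mda
import numpy as np
from MDAnalysis.coordinates.memory import MemoryReader

from ._geom import fit_cylinder_axis, rotation_about_axis, segment_axis_angle
from .errors import ParameterError, ScheduleError, SelectionError, TopologyError
from .topology import ONE_TO_THREE, ComplexTopology, default_topology

__all__ = [
    "HelixSpec", "KinkSpec", "OccupancySchedule", "ChainStructure",
    "build_ideal_helix", "apply_kink", "place_sidechain_probes",
    "build_chain", "build_assembly", "generate_trajectory",
    "write_trajectory", "read_trajectory", "reference_systems",
    "reference_schedules", "segment_axis_angle",
    "ON_DISTANCE", "OFF_DISTANCE",
]

#: donor–acceptor distance on frames where a schedule is satisfied (Å)
ON_DISTANCE = 2.8
#: donor–acceptor distance on frames where a schedule is violated (Å)
OFF_DISTANCE = 5.0

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# cylinder parameters (radius scale rel. to Cα radius, phase offset deg,
# z offset Å) for the non-Cα backbone atoms of the idealised helix
_BACKBONE_GEOMETRY = {
    "N": (1.5 / 2.3, -28.0, -0.9),
    "C": (1.6 / 2.3, +27.0, +0.8),
    "O": (2.0 / 2.3, +29.0, +2.0),
}

# idealised probe offsets from the parent Cα (Å); stand-ins for extended
# side chains, kept short so unscheduled cross-chain atoms never touch
PROBE_OFFSETS = {
    ("K", "NZ"): 3.0,
    ("D", "OD1"): 2.0,
    ("D", "OD2"): 2.2,
    ("T", "OG1"): 1.5,
    ("W", "NE1"): 2.5,
}
_HYDROGENS = {"NZ": ("HZ1", "HZ2", "HZ3"), "NE1": ("HE1",)}
_H_BOND_LENGTH = 1.0
_H_CONE_DEG = 25.0       # half-angle of the hydrogen cone about the probe axis
_TILT_DEG = 10.0         # acceptor placement tilt off the hydrogen direction

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "NZ": "N", "OD1": "O",
            "OD2": "O", "OG1": "O", "NE1": "N", "HZ1": "H", "HZ2": "H",
            "HZ3": "H", "HE1": "H"}

# default bundle placement: receptor chain C at the origin, the two adaptor
# chains on the ±x axis, z-staggered so the adaptor D16 Cα sits at the same
# height as the receptor K26 Cα
DEFAULT_PLACEMENTS = {
    "C": (0.0, 0.0, 0.0),
    "A": (13.5, 0.0, 15.0),
    "B": (-13.5, 0.0, 15.0),
}


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of an ideal α-helix.

    Defaults are the textbook values: 1.5 Å rise, 2.3 Å Cα radius and
    100° twist per residue (3.6 residues/turn).
    """

    n_residues: int
    rise_per_residue: float = 1.5
    radius: float = 2.3
    twist_per_residue: float = 100.0
    sequence: str | None = None

    def __post_init__(self):
        if self.n_residues < 5:
            raise ParameterError(f"n_residues must be >= 5, got {self.n_residues}")
        if self.rise_per_residue <= 0:
            raise ParameterError(f"rise_per_residue must be > 0, got {self.rise_per_residue}")
        if self.radius < 0:
            raise ParameterError(f"radius must be >= 0, got {self.radius}")
        if not 0 < self.twist_per_residue < 360:
            raise ParameterError(
                f"twist_per_residue must be in (0, 360), got {self.twist_per_residue}")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ParameterError(
                f"sequence length {len(self.sequence)} != n_residues {self.n_residues}")


@dataclass(frozen=True)
class KinkSpec:
    """A programmed helix bend: ground truth for kink-angle recovery.

    ``hinge_residue`` is the 1-based residue at which the helix bends;
    residues beyond it rotate rigidly by ``kink_angle`` about an axis
    through the hinge Cα perpendicular to the local helix axis.
    ``kink_plane_azimuth`` selects the orientation of that rotation axis
    (0° bends the C-terminal segment toward −y for a +z helix).
    """

    hinge_residue: int
    kink_angle: float
    kink_plane_azimuth: float = 0.0

    def __post_init__(self):
        if not 0 <= self.kink_angle <= 180:
            raise ParameterError(f"kink_angle must be in [0, 180], got {self.kink_angle}")

    def validate_for(self, n_residues: int, first_resid: int = 1) -> None:
        pos = self.hinge_residue - first_resid + 1  # 1-based position in helix
        if not (5 <= pos <= n_residues - 4):
            raise ParameterError(
                f"hinge_residue {self.hinge_residue} too close to the helix ends "
                f"(need >= 4 residues on either side of a {n_residues}-residue helix)")


@dataclass
class OccupancySchedule:
    """Frame-by-frame ground truth for one donor→acceptor hydrogen bond.

    ``mode='quota'`` realises exactly ``round(target_occupancy · n_frames)``
    satisfying frames (seeded random positions); ``mode='bernoulli'`` draws
    each frame independently with probability ``target_occupancy``.
    """

    donor: tuple[str, int, str]      # (chain, resid, atom)
    acceptor: tuple[str, int, str]
    target_occupancy: float
    hydrogen: str | None = None      # auto-assigned from the donor if None
    mode: str = "quota"
    frame_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ParameterError(
                f"target_occupancy must be in [0, 1], got {self.target_occupancy}")
        if self.mode not in ("quota", "bernoulli"):
            raise ParameterError(f"mode must be 'quota' or 'bernoulli', got {self.mode!r}")

    @property
    def pair_id(self) -> tuple:
        return (self.donor, self.hydrogen, self.acceptor)

    @property
    def label(self) -> str:
        return f"{self.donor[2]}-{self.acceptor[2]}"

    def realize_mask(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "quota":
            k = int(round(self.target_occupancy * n_frames))
            mask = np.zeros(n_frames, dtype=bool)
            mask[rng.permutation(n_frames)[:k]] = True
        else:
            mask = rng.random(n_frames) < self.target_occupancy
        self.frame_mask = mask
        return mask


@dataclass
class ChainStructure:
    """Flat per-atom arrays for one chain; the unit the builders operate on."""

    chain_id: str
    resids: np.ndarray
    resnames: list[str]
    names: list[str]
    elements: list[str]
    positions: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_index(self, resid: int, name: str) -> int:
        for i in range(self.n_atoms):
            if self.resids[i] == resid and self.names[i] == name:
                return i
        raise SelectionError(f"no atom {name} in residue {resid} of chain {self.chain_id}")

    def ca_coordinates(self) -> np.ndarray:
        idx = [i for i, n in enumerate(self.names) if n == "CA"]
        return self.positions[idx]


def build_ideal_helix(spec: HelixSpec) -> dict[str, np.ndarray]:
    """Backbone coordinates (N, CA, C, O; shape (n_residues, 3) each) of an
    ideal parametric helix with its axis along +z and residue i at height
    (i−1)·rise."""
    k = np.arange(spec.n_residues, dtype=float)
    tau = np.deg2rad(spec.twist_per_residue)
    out = {}
    out["CA"] = np.column_stack([
        spec.radius * np.cos(k * tau),
        spec.radius * np.sin(k * tau),
        k * spec.rise_per_residue,
    ])
    for name, (rscale, dphi, dz) in _BACKBONE_GEOMETRY.items():
        phi = k * tau + np.deg2rad(dphi)
        r = spec.radius * rscale
        out[name] = np.column_stack([
            r * np.cos(phi), r * np.sin(phi), k * spec.rise_per_residue + dz])
    return out


def _local_axis(ca: np.ndarray, hinge_pos: int) -> np.ndarray:
    """Axis of the pre-hinge segment (ground-truth +z for ideal input)."""
    return fit_cylinder_axis(ca[:hinge_pos])


def apply_kink(chain: ChainStructure, kink: KinkSpec) -> ChainStructure:
    """Rotate all residues beyond the hinge rigidly by ``kink.kink_angle``.

    The rotation axis passes through the hinge Cα, perpendicular to the
    local (pre-hinge) helix axis, oriented by ``kink_plane_azimuth``.
    Residues at or before the hinge are untouched; a zero angle is the
    identity.  Returns a new :class:`ChainStructure`.
    """
    first_resid = int(chain.resids.min())
    n_res = len(set(chain.resids.tolist()))
    kink.validate_for(n_res, first_resid)

    ca = chain.ca_coordinates()
    hinge_pos = kink.hinge_residue - first_resid + 1
    axis_z = _local_axis(ca, hinge_pos)
    # azimuth reference frame perpendicular to the local axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_z)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis_z) * axis_z
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_z, e1)
    az = np.deg2rad(kink.kink_plane_azimuth)
    rot_axis = np.cos(az) * e1 + np.sin(az) * e2

    pivot = ca[hinge_pos - 1]
    rot = rotation_about_axis(rot_axis, kink.kink_angle)
    moving = chain.resids > kink.hinge_residue
    positions = chain.positions.copy()
    positions[moving] = rot.apply(positions[moving] - pivot) + pivot
    return ChainStructure(chain.chain_id, chain.resids.copy(), list(chain.resnames),
                          list(chain.names), list(chain.elements), positions)


def _probe_frame(ca: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(radial, axial, tangent) orthonormal frame at a Cα for probe placement."""
    radial = ca - np.dot(ca, axis) * axis
    n = np.linalg.norm(radial)
    if n < 1e-9:  # Cα on the axis (radius-0 helix): pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, axis)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        radial = ref - np.dot(ref, axis) * axis
        n = np.linalg.norm(radial)
    radial = radial / n
    tangent = np.cross(axis, radial)
    return radial, axis, tangent


def probe_atoms_for(letter: str) -> list[str]:
    """Names of the side-chain probe atoms placed on a residue type."""
    out = [a for (lt, a) in PROBE_OFFSETS if lt == letter]
    for a in list(out):
        out.extend(_HYDROGENS.get(a, ()))
    return out


def place_sidechain_probes(chain: ChainStructure, center: np.ndarray | None = None) -> ChainStructure:
    """Append idealised side-chain donor/acceptor atoms to a backbone chain.

    Probes point radially outward from the helix axis at their residue's
    azimuth; lysine HZ1–HZ3 sit on a 25° cone about the NZ direction and the
    tryptophan HE1 extends the NE1 direction.  Requesting a probe for a
    residue type that does not carry it raises :class:`TopologyError`
    (via :func:`probe_position`).
    """
    ca_all = chain.ca_coordinates()
    axis = fit_cylinder_axis(ca_all) if len(ca_all) >= 5 else np.array([0.0, 0.0, 1.0])
    if center is None:
        center = ca_all.mean(axis=0)

    resids, resnames, names, elements, positions = [], [], [], [], []
    first_resid = int(chain.resids.min())
    for i in range(chain.n_atoms):
        resids.append(chain.resids[i])
        resnames.append(chain.resnames[i])
        names.append(chain.names[i])
        elements.append(chain.elements[i])
        positions.append(chain.positions[i])
        if chain.names[i] != "O":   # append probes after the residue backbone
            continue
        resid = int(chain.resids[i])
        letter = _letter_of(chain.resnames[i])
        ca = ca_all[resid - first_resid]
        for atom in probe_atoms_for(letter):
            if atom.startswith("H"):
                continue  # hydrogens handled with their parent below
            pos = probe_position(letter, atom, ca, axis)
            resids.append(resid)
            resnames.append(chain.resnames[i])
            names.append(atom)
            elements.append(_ELEMENT[atom])
            positions.append(pos)
            for j, hname in enumerate(_HYDROGENS.get(atom, ())):
                hdir = _hydrogen_direction(ca, axis, j, len(_HYDROGENS[atom]))
                resids.append(resid)
                resnames.append(chain.resnames[i])
                names.append(hname)
                elements.append("H")
                positions.append(pos + _H_BOND_LENGTH * hdir)
    return ChainStructure(chain.chain_id, np.array(resids), resnames, names,
                          elements, np.array(positions))


def probe_position(letter: str, atom: str, ca: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Idealised position of side-chain probe ``atom`` for residue type
    ``letter`` whose Cα is at ``ca`` on a helix with unit ``axis``."""
    if (letter, atom) not in PROBE_OFFSETS:
        raise TopologyError(f"atom {atom!r} is not defined for residue type {letter!r}")
    radial, axial, _ = _probe_frame(ca, axis)
    offset = PROBE_OFFSETS[(letter, atom)]
    # split OD1/OD2 (and nothing else) slightly along the axis so they differ
    tilt = {"OD1": +20.0, "OD2": -20.0}.get(atom, 0.0)
    t = np.deg2rad(tilt)
    direction = np.cos(t) * radial + np.sin(t) * axial
    return ca + offset * direction


def _hydrogen_direction(ca: np.ndarray, axis: np.ndarray, j: int, n_h: int) -> np.ndarray:
    radial, axial, tangent = _probe_frame(ca, axis)
    if n_h == 1:
        return radial
    cone = np.deg2rad(_H_CONE_DEG)
    az = 2 * np.pi * j / n_h
    return (np.cos(cone) * radial
            + np.sin(cone) * (np.cos(az) * axial + np.sin(az) * tangent))


def _letter_of(resname: str) -> str:
    from .topology import THREE_TO_ONE
    return THREE_TO_ONE[resname]


def build_chain(chain_id: str, sequence: str, helix: HelixSpec | None = None,
                kink: KinkSpec | None = None, offset=(0.0, 0.0, 0.0),
                first_resid: int = 1, probes: bool = True) -> ChainStructure:
    """Build one helical chain: ideal backbone, optional probes, optional
    kink, then a rigid translation to its place in the bundle."""
    spec = helix or HelixSpec(n_residues=len(sequence), sequence=sequence)
    if spec.sequence is None:
        spec = HelixSpec(spec.n_residues, spec.rise_per_residue, spec.radius,
                         spec.twist_per_residue, sequence)
    backbone = build_ideal_helix(spec)

    resids, resnames, names, elements, positions = [], [], [], [], []
    for i, letter in enumerate(sequence):
        for atom in BACKBONE_ATOMS:
            resids.append(first_resid + i)
            resnames.append(ONE_TO_THREE[letter])
            names.append(atom)
            elements.append(_ELEMENT[atom])
            positions.append(backbone[atom][i])
    chain = ChainStructure(chain_id, np.array(resids), resnames, names,
                           elements, np.array(positions))
    if probes:
        chain = place_sidechain_probes(chain)
    if kink is not None:
        chain = apply_kink(chain, kink)
    chain.positions = chain.positions + np.asarray(offset, dtype=float)
    return chain


def chains_to_universe(chains: list[ChainStructure]) -> mda.Universe:
    """Assemble chain structures into a single-frame MDAnalysis Universe."""
    n_atoms = sum(c.n_atoms for c in chains)
    resindex, res_resids, res_resnames, res_chains = [], [], [], []
    chain_ids, names, elements, positions = [], [], [], []
    seg_of_res = []
    ires = -1
    for iseg, c in enumerate(chains):
        last = None
        for i in range(c.n_atoms):
            if c.resids[i] != last:
                ires += 1
                last = c.resids[i]
                res_resids.append(int(c.resids[i]))
                res_resnames.append(c.resnames[i])
                res_chains.append(c.chain_id)
                seg_of_res.append(iseg)
            resindex.append(ires)
            chain_ids.append(c.chain_id)
            names.append(c.names[i])
            elements.append(c.elements[i])
            positions.append(c.positions[i])
    u = mda.Universe.empty(n_atoms, n_residues=len(res_resids),
                           atom_resindex=np.array(resindex),
                           residue_segindex=np.array(seg_of_res),
                           n_segments=len(chains), trajectory=True)
    u.add_TopologyAttr("name", names)
    u.add_TopologyAttr("resname", res_resnames)
    u.add_TopologyAttr("resid", res_resids)
    u.add_TopologyAttr("chainIDs", chain_ids)
    u.add_TopologyAttr("segids", [c.chain_id for c in chains])
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("occupancies", [1.0] * n_atoms)
    u.add_TopologyAttr("tempfactors", [0.0] * n_atoms)
    u.atoms.positions = np.asarray(positions, dtype=np.float32)
    return u


def build_assembly(topology: ComplexTopology | None = None,
                   kinks: dict[str, KinkSpec] | None = None,
                   placements: dict[str, tuple] | None = None) -> mda.Universe:
    """Build the three-chain bundle as a single-frame Universe.

    ``kinks`` maps chain id to a :class:`KinkSpec`; ``placements`` maps chain
    id to a rigid (x, y, z) offset, defaulting to the receptor at the origin
    and the adaptor chains at ±13.5 Å on x, z-staggered by +15 Å.
    """
    topology = topology or default_topology()
    kinks = kinks or {}
    placements = {**DEFAULT_PLACEMENTS, **(placements or {})}
    chains = []
    for cd in topology.chains:
        chains.append(build_chain(cd.chain_id, cd.sequence,
                                  kink=kinks.get(cd.chain_id),
                                  offset=placements.get(cd.chain_id, (0, 0, 0)),
                                  first_resid=cd.first_resid))
    return chains_to_universe(chains)


def _select_one(u: mda.Universe, chain: str, resid: int, name: str) -> int:
    ag = u.select_atoms(f"chainID {chain} and resid {resid} and name {name}")
    if len(ag) != 1:
        raise SelectionError(
            f"expected exactly one atom for chain {chain} resid {resid} name {name}, "
            f"found {len(ag)}")
    return int(ag.ix[0])


def _tilted_direction(base: np.ndarray, tilt_deg: float, tilt_azimuth_deg: float) -> np.ndarray:
    """Unit vector at ``tilt_deg`` from ``base``, azimuth chosen about it."""
    b = base / np.linalg.norm(base)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, b)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(b, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(b, e1)
    t = np.deg2rad(tilt_deg)
    az = np.deg2rad(tilt_azimuth_deg)
    return np.cos(t) * b + np.sin(t) * (np.cos(az) * e1 + np.sin(az) * e2)


def generate_trajectory(assembly: mda.Universe, n_frames: int,
                        noise_sigma: float = 0.1,
                        schedules: list[OccupancySchedule] | None = None,
                        seed: int = 0, dt_ns: float = 1.0) -> tuple[mda.Universe, dict]:
    """Generate an in-memory trajectory from a single-frame assembly.

    Returns ``(universe, ground_truth)`` where ``ground_truth`` is a
    JSON-serialisable record of the seed, the noise level and every
    schedule's realised frame mask.  Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    if noise_sigma < 0:
        raise ParameterError(f"noise_sigma must be >= 0, got {noise_sigma}")
    schedules = list(schedules or [])
    rng = np.random.default_rng(seed)

    # resolve schedule atoms, auto-assign hydrogens, detect conflicts
    donor_h_counter: dict[tuple, int] = {}
    resolved = []   # (schedule, donor_idx, hydrogen_idx, acceptor_idx, tilt_azimuth)
    used_acceptors: set = set()
    for k, s in enumerate(schedules):
        di = _select_one(assembly, *s.donor)
        hyds = _HYDROGENS.get(s.donor[2])
        if hyds is None:
            raise ScheduleError(f"donor atom {s.donor} carries no hydrogens")
        if s.hydrogen is None:
            j = donor_h_counter.get(s.donor, 0)
            s.hydrogen = hyds[j % len(hyds)]
            donor_h_counter[s.donor] = j + 1
        elif s.hydrogen not in hyds:
            raise ScheduleError(f"hydrogen {s.hydrogen!r} not attached to donor {s.donor}")
        hi = _select_one(assembly, s.donor[0], s.donor[1], s.hydrogen)
        ai = _select_one(assembly, *s.acceptor)
        if ai in used_acceptors:
            raise ScheduleError(f"conflicting schedules move the same acceptor atom {s.acceptor}")
        if ai in (di, hi):
            raise ScheduleError(f"schedule {s.label} uses the same atom as donor and acceptor")
        used_acceptors.add(ai)
        resolved.append((s, di, hi, ai, (137.5 * k) % 360.0))
    donor_atoms = {di for (_, di, _, _, _) in resolved} | {hi for (_, _, hi, _, _) in resolved}
    if used_acceptors & donor_atoms:
        raise ScheduleError("an acceptor atom of one schedule is a donor/hydrogen of another")

    base = assembly.atoms.positions.astype(float)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma, size=coords.shape)
        exempt = sorted(used_acceptors | donor_atoms)
        noise[:, exempt, :] = 0.0
        coords += noise

    truth_schedules = []
    for s, di, hi, ai, tilt_az in resolved:
        mask = s.realize_mask(n_frames, rng)
        direction = _tilted_direction(base[hi] - base[di], _TILT_DEG, tilt_az)
        coords[mask, ai, :] = base[di] + ON_DISTANCE * direction
        coords[~mask, ai, :] = base[di] + OFF_DISTANCE * direction
        truth_schedules.append({
            "donor": list(s.donor), "hydrogen": s.hydrogen,
            "acceptor": list(s.acceptor), "label": s.label,
            "target_occupancy": s.target_occupancy, "mode": s.mode,
            "realized_occupancy": float(mask.mean()),
            "frame_mask": mask.astype(int).tolist(),
        })

    u = mda.Merge(assembly.atoms)
    u.load_new(coords.astype(np.float32), format=MemoryReader, dt=dt_ns)
    truth = {
        "seed": int(seed), "n_frames": int(n_frames),
        "noise_sigma": float(noise_sigma), "dt_ns": float(dt_ns),
        "on_distance": ON_DISTANCE, "off_distance": OFF_DISTANCE,
        "schedules": truth_schedules,
    }
    return u, truth


def write_trajectory(u: mda.Universe, prefix: str | Path,
                     ground_truth: dict | None = None,
                     formats: tuple[str, ...] = ("pdb",)) -> dict[str, Path]:
    """Write topology PDB + multi-model PDB trajectory (+ optional DCD) and
    a JSON ground-truth sidecar.  Returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = prefix.with_name(prefix.name + "_top.pdb")
        u.trajectory[0]
        u.atoms.write(str(top))
        paths["topology"] = top

        traj = prefix.with_name(prefix.name + "_traj.pdb")
        with mda.Writer(str(traj), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        paths["trajectory"] = traj

        if "dcd" in formats:
            dcd = prefix.with_name(prefix.name + "_traj.dcd")
            with mda.Writer(str(dcd), n_atoms=len(u.atoms)) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
            paths["dcd"] = dcd

    if ground_truth is not None:
        sidecar = prefix.with_name(prefix.name + "_truth.json")
        sidecar.write_text(json.dumps(ground_truth, indent=1, sort_keys=True))
        paths["ground_truth"] = sidecar
    return paths


def read_trajectory(topology: str | Path, trajectory: str | Path) -> mda.Universe:
    """Load a written system back; the inverse of :func:`write_trajectory`."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(topology), str(trajectory))


def reference_schedules(system: str, quota: bool = True) -> list[OccupancySchedule]:
    """Interface H-bond schedules for the three reference systems.

    Target occupancies mirror the published per-bond probabilities of the
    kinked (6z0g-derived), unkinked (6z0i-derived) and AlphaFold-derived
    complexes, expressed as fractions.
    """
    mode = "quota" if quota else "bernoulli"

    def s(d_resid, d_atom, chain, a_resid, a_atom, p):
        return OccupancySchedule(donor=("C", d_resid, d_atom),
                                 acceptor=(chain, a_resid, a_atom),
                                 target_occupancy=p, mode=mode)

    table = {
        "6z0g_like": [
            s(26, "NZ", "A", 16, "OD1", 0.3474),
            s(26, "NZ", "A", 16, "OD2", 0.4457),
            s(26, "NZ", "A", 20, "OG1", 0.1510),
        ],
        "6z0i_like": [
            s(26, "NZ", "A", 16, "OD1", 0.2485),
            s(26, "NZ", "A", 16, "OD2", 0.6035),
            s(26, "NZ", "B", 16, "OD1", 0.3491),
            s(26, "NZ", "B", 16, "OD2", 0.4303),
        ],
        "af_like": [
            s(26, "NZ", "A", 16, "OD1", 0.3286),
            s(26, "NZ", "A", 16, "OD2", 0.3849),
            s(34, "NE1", "A", 20, "OG1", 0.0055),
            s(34, "NE1", "A", 20, "O", 0.0908),
            s(26, "NZ", "B", 16, "OD1", 0.3329),
            s(26, "NZ", "B", 16, "OD2", 0.3478),
            s(26, "NZ", "B", 20, "OG1", 0.0102),
        ],
    }
    if system not in table:
        raise ParameterError(f"unknown reference system {system!r}; "
                             f"choose from {sorted(table)}")
    return table[system]


def reference_systems(seed: int = 0, n_frames: int = 301, noise_sigma: float = 0.1,
                      quota: bool = True):
    """Build the three standard synthetic systems.

    * ``6z0g_like`` — receptor kinked 100° at residue 26 (bend away from
      both adaptor chains), adaptor chain B placed out of contact range:
      the single-chain-engagement state.
    * ``6z0i_like`` and ``af_like`` — straight receptor engaging both
      adaptor chains symmetrically.

    Returns ``{name: (topology, universe, ground_truth)}``; per-system seeds
    are derived deterministically from ``seed``.
    """
    topo = default_topology()
    out = {}
    specs = {
        "6z0g_like": dict(
            kinks={"C": KinkSpec(hinge_residue=26, kink_angle=100.0)},
            placements={"B": (-18.0, 0.0, 15.0)},
        ),
        "6z0i_like": dict(kinks=None, placements=None),
        "af_like": dict(kinks=None, placements=None),
    }
    for i, (name, kw) in enumerate(specs.items()):
        assembly = build_assembly(topo, kinks=kw["kinks"], placements=kw["placements"])
        u, truth = generate_trajectory(
            assembly, n_frames=n_frames, noise_sigma=noise_sigma,
            schedules=reference_schedules(name, quota=quota),
            seed=(seed * 7919 + i) % (2**31), dt_ns=1.0)
        if kw["kinks"]:
            ks = kw["kinks"]["C"]
            truth["kink"] = {"chain": "C", "hinge_residue": ks.hinge_residue,
                             "kink_angle": ks.kink_angle,
                             "kink_plane_azimuth": ks.kink_plane_azimuth}
        out[name] = (topo, u, truth)
    return out
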