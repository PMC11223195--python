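"""Per-frame kink angle of the receptor transmembrane helix.

The kink metric is the published 4-point Cα construction: the angle between
v1 = Cα(vec1_end) − Cα(vec1_start) (default A20→L24, below the hinge) and
v2 = Cα(vec2_end) − Cα(vec2_start) (default A32→A36, above it).  Note that a
perfectly straight ideal helix does *not* measure 0° with this metric: a
4-residue Cα displacement is tilted ~14.7° off the helix axis, so two such
vectors 12 residues apart enclose ~25.4° even without any bend.  That
systematic offset is a property of the metric itself and is what makes
unkinked helices report ~37–40° in real structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import MDAnalysis as mda
import numpy as np

from ._geom import angle_between
from .errors import InputError, SelectionError

__all__ = ["KinkVectorSpec", "KinkSeries", "kink_angle", "kink_series"]


@dataclass(frozen=True)
class KinkVectorSpec:
    """The four Cα anchors of the kink metric, on one chain.

    Defaults follow the published choice: residues 20 and 24 span the
    first vector, 32 and 36 the second, on the receptor chain C.
    """

    chain: str = "C"
    vec1_start: int = 20
    vec1_end: int = 24
    vec2_start: int = 32
    vec2_end: int = 36

    def __post_init__(self):
        if self.vec1_start == self.vec1_end or self.vec2_start == self.vec2_end:
            raise SelectionError("kink vector endpoints must be distinct residues")


@dataclass
class KinkSeries:
    """Per-frame kink angles with summary statistics.

    ``mean_error`` is the standard error of the mean over frames; ``mode``
    is the centre of the most populated histogram bin (bins of width
    ``bin_width`` anchored at 0°, ties broken toward the lower bin).
    """

    angles: np.ndarray
    bin_width: float = 1.0
    mean: float = field(init=False)
    mean_error: float = field(init=False)
    mode: float = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.size == 0:
            raise InputError("cannot summarise an empty angle series")
        self.angles = a
        self.mean = float(a.mean())
        self.mean_error = float(a.std(ddof=0) / np.sqrt(a.size))
        idx = np.floor(a / self.bin_width).astype(int)
        counts = np.bincount(idx)
        self.mode = float((int(counts.argmax()) + 0.5) * self.bin_width)

    @property
    def n_frames(self) -> int:
        return int(self.angles.size)


def _ca_position(u: mda.Universe, chain: str, resid: int) -> np.ndarray:
    ag = u.select_atoms(f"chainID {chain} and resid {resid} and name CA")
    if len(ag) != 1:
        raise SelectionError(f"no unique CA atom for residue {resid} on chain {chain}")
    return ag.positions[0].astype(float)


def kink_angle(u: mda.Universe, spec: KinkVectorSpec | None = None) -> float:
    """Kink angle (degrees, in [0, 180]) for the universe's current frame."""
    spec = spec or KinkVectorSpec()
    v1 = (_ca_position(u, spec.chain, spec.vec1_end)
          - _ca_position(u, spec.chain, spec.vec1_start))
    v2 = (_ca_position(u, spec.chain, spec.vec2_end)
          - _ca_position(u, spec.chain, spec.vec2_start))
    return angle_between(v1, v2)


def kink_series(u: mda.Universe, spec: KinkVectorSpec | None = None,
                bin_width: float = 1.0,
                frames: tuple[int, int] | None = None) -> KinkSeries:
    """Kink angle over the trajectory (optionally an inclusive frame window)."""
    spec = spec or KinkVectorSpec()
    n = len(u.trajectory)
    if n == 0:
        raise InputError("trajectory has no frames")
    start, stop = (0, n - 1) if frames is None else frames
    # resolve the four atoms once; only positions change per frame
    atoms = [u.select_atoms(f"chainID {spec.chain} and resid {r} and name CA")
             for r in (spec.vec1_start, spec.vec1_end, spec.vec2_start, spec.vec2_end)]
    for r, ag in zip((spec.vec1_start, spec.vec1_end, spec.vec2_start, spec.vec2_end), atoms):
        if len(ag) != 1:
            raise SelectionError(f"no unique CA atom for residue {r} on chain {spec.chain}")
    angles = np.empty(stop - start + 1)
    for i, _ in enumerate(u.trajectory[start:stop + 1]):
        p = [ag.positions[0].astype(float) for ag in atoms]
        angles[i] = angle_between(p[1] - p[0], p[3] - p[2])
    return KinkSeries(angles=angles, bin_width=bin_width)
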