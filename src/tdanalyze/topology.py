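"""Chain roles and residue identities for a receptor/adaptor TM helix trimer.

The complexes analysed here are TREM2/DAP12-like bundles: one receptor helix
(TREM2, carrying the charged lysine K26 and the disease-relevant tryptophan
W34) packed against the two chains of an adaptor homodimer (DAP12, each chain
carrying the DxxxT motif residues D16 and T20).  :class:`ComplexTopology`
records which chain plays which role and what the residue identities are, so
the analysis modules can resolve "K26 on the receptor chain" to concrete
atoms without hard-coding chain ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, TopologyError

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: Residues counted as hydrophobic for interface classification.  Trp is
#: included (it acts as a hydrophobic partner at this interface); Gly is not.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWP")

#: Side-chain charge signs used for salt-bridge identity checks.
RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

RECEPTOR = "receptor"
ADAPTOR = "adaptor"

_ROLE_ALIASES = {
    "receptor": RECEPTOR, "trem2": RECEPTOR,
    "adaptor": ADAPTOR, "dap12": ADAPTOR,
}


def _default_receptor_sequence(n: int = 40) -> str:
    """Poly-alanine receptor helix with the key TREM2 residues substituted
    at their published numbering (L19, L24, K26, W34; A20/A32/A36 are
    already alanine)."""
    seq = ["A"] * n
    for resid, letter in {19: "L", 24: "L", 26: "K", 34: "W"}.items():
        seq[resid - 1] = letter
    return "".join(seq)


def _default_adaptor_sequence(n: int = 36) -> str:
    """Poly-alanine adaptor helix with the key DAP12 residues substituted
    (I12, D16, T20, I23; A24/A27 already alanine)."""
    seq = ["A"] * n
    for resid, letter in {12: "I", 16: "D", 20: "T", 23: "I"}.items():
        seq[resid - 1] = letter
    return "".join(seq)


@dataclass(frozen=True)
class ChainDef:
    """One chain of the complex: id, role and one-letter sequence."""

    chain_id: str
    role: str
    sequence: str
    first_resid: int = 1

    def __post_init__(self):
        role = _ROLE_ALIASES.get(self.role.lower())
        if role is None:
            raise ConfigError(f"unknown chain role {self.role!r}")
        object.__setattr__(self, "role", role)
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise TopologyError(f"unknown residue letters {bad!r} in chain {self.chain_id}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def resids(self) -> range:
        return range(self.first_resid, self.first_resid + self.n_residues)

    def letter(self, resid: int) -> str:
        if resid not in self.resids:
            raise TopologyError(f"resid {resid} outside chain {self.chain_id} "
                                f"({self.first_resid}..{self.resids[-1]})")
        return self.sequence[resid - self.first_resid]


@dataclass(frozen=True)
class ComplexTopology:
    """Chain role assignment for a receptor + adaptor-dimer helix bundle."""

    chains: tuple[ChainDef, ...] = field(default_factory=tuple)

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate chain ids in {ids}")
        if len(self.receptor_chains) != 1:
            raise ConfigError(
                f"exactly one receptor-role chain required, got {len(self.receptor_chains)}")
        if len(self.adaptor_chains) != 2:
            raise ConfigError(
                f"exactly two adaptor-role chains required, got {len(self.adaptor_chains)}")

    @property
    def receptor_chains(self) -> tuple[ChainDef, ...]:
        return tuple(c for c in self.chains if c.role == RECEPTOR)

    @property
    def adaptor_chains(self) -> tuple[ChainDef, ...]:
        return tuple(c for c in self.chains if c.role == ADAPTOR)

    @property
    def receptor(self) -> ChainDef:
        return self.receptor_chains[0]

    def chain(self, chain_id: str) -> ChainDef:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise TopologyError(f"no chain {chain_id!r} in topology")

    def letter(self, chain_id: str, resid: int) -> str:
        return self.chain(chain_id).letter(resid)


def default_topology() -> ComplexTopology:
    """The standard synthetic trimer: receptor chain C, adaptor chains A/B."""
    return ComplexTopology(chains=(
        ChainDef("A", ADAPTOR, _default_adaptor_sequence()),
        ChainDef("B", ADAPTOR, _default_adaptor_sequence()),
        ChainDef("C", RECEPTOR, _default_receptor_sequence()),
    ))
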