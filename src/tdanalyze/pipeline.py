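"""End-to-end orchestration: read systems, run all analyses, emit tables.

``run_all`` reproduces the full analysis flow over one to three configured
systems: per-frame kink series for the receptor helix, Cα (11 Å) contact
maps against each adaptor chain over the configured window, persistent
all-atom (3 Å) maps, the six-map consensus contact set with interaction
classification, per-entry H-bond occupancies and per-frame H-bond counts.
All outputs are plain CSV/JSON with a provenance header, and a run is
byte-reproducible given the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import MDAnalysis as mda
import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._geom import round_half_up
from .contacts import (ContactMap, classify_interactions, consensus_merge,
                       contact_map, persistence_filter)
from .errors import ConfigError, InputError
from .geometry import KinkVectorSpec, kink_series
from .hbonds import HBondCriteria, default_registry, hbond_count_series, occupancy_table
from .topology import ChainDef, ComplexTopology

__all__ = ["SystemSpec", "AnalysisConfig", "RunReport", "read_system",
           "run_all", "parse_window", "topology_from_universe"]

_WINDOW_RE = re.compile(r"^\s*([\d.]+)\s*(ns)?\s*:\s*([\d.]+)\s*(ns)?\s*$")


@dataclass(frozen=True)
class SystemSpec:
    """One trajectory to analyse.

    ``window`` restricts the *contact-map* analyses (the published Cα maps
    use a 175–225 ns window); kink and H-bond statistics always use the
    full trajectory.  Accepted forms: ``"175ns:225ns"`` (time, converted
    with ``dt_ns`` per frame) or ``"10:50"`` (frame indices); both ends
    inclusive.
    """

    name: str
    topology: str
    trajectory: str
    window: str | None = None
    dt_ns: float = 1.0


@dataclass
class AnalysisConfig:
    """Full configuration for :func:`run_all`; defaults are the published
    analysis parameters."""

    systems: list[SystemSpec]
    chain_roles: dict[str, str] = field(
        default_factory=lambda: {"C": "TREM2", "A": "DAP12", "B": "DAP12"})
    kink_vectors: KinkVectorSpec = field(default_factory=KinkVectorSpec)
    ca_cutoff: float = 11.0
    aa_cutoff: float = 3.0
    persistence_threshold: float = 0.5
    consensus_min_count: int = 3
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    salt_bridge_cutoff: float = 4.0
    bin_width: float = 1.0
    out_dir: str = "tdanalyze_out"
    seed: int = 0

    def __post_init__(self):
        if not self.systems:
            raise ConfigError("at least one system must be configured")
        roles = [r.lower() for r in self.chain_roles.values()]
        if roles.count("trem2") + roles.count("receptor") != 1:
            raise ConfigError("exactly one chain must have the TREM2/receptor role")
        if roles.count("dap12") + roles.count("adaptor") != 2:
            raise ConfigError("exactly two chains must have the DAP12/adaptor role")
        if not 0 <= self.persistence_threshold < 1:
            raise ConfigError(
                f"persistence_threshold must be in [0, 1), got {self.persistence_threshold}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        systems = [SystemSpec(**s) for s in raw.pop("systems")]
        kv = raw.pop("kink_vectors", None)
        hb = raw.pop("hbond", None)
        kwargs = dict(raw)
        if kv:
            kwargs["kink_vectors"] = KinkVectorSpec(
                chain=kv.get("chain", "C"),
                vec1_start=kv.get("vec1", [20, 24])[0], vec1_end=kv.get("vec1", [20, 24])[1],
                vec2_start=kv.get("vec2", [32, 36])[0], vec2_end=kv.get("vec2", [32, 36])[1])
        if hb:
            kwargs["hbond_criteria"] = HBondCriteria(**hb)
        return cls(systems=systems, **kwargs)

    def content_hash(self) -> str:
        blob = json.dumps({
            "systems": [[s.name, s.window, s.dt_ns] for s in self.systems],
            "chain_roles": self.chain_roles, "ca": self.ca_cutoff, "aa": self.aa_cutoff,
            "persist": self.persistence_threshold, "consensus": self.consensus_min_count,
            "hbond": [self.hbond_criteria.distance_cutoff, self.hbond_criteria.angle_cutoff,
                      self.hbond_criteria.distance_definition],
            "kink": [self.kink_vectors.chain, self.kink_vectors.vec1_start,
                     self.kink_vectors.vec1_end, self.kink_vectors.vec2_start,
                     self.kink_vectors.vec2_end],
            "bin": self.bin_width, "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """What a run produced: summaries, file paths and notices."""

    out_dir: Path
    provenance: dict
    systems: dict
    consensus: dict | None
    notices: list[str]

    def to_json(self) -> str:
        payload = {"provenance": self.provenance, "systems": self.systems,
                   "consensus": self.consensus, "notices": self.notices}
        return json.dumps(payload, indent=1, sort_keys=True)


def parse_window(window: str | None, dt_ns: float, n_frames: int) -> tuple[int, int] | None:
    """Resolve a window string to an inclusive frame range.

    Time windows map to frames with both ends inclusive; the start maps to
    the nearest frame at or after the start time, the stop to the last
    frame at or before the stop time.
    """
    if window is None:
        return None
    m = _WINDOW_RE.match(str(window))
    if not m:
        raise ConfigError(f"cannot parse window {window!r}; expected 'A:B' or 'Ans:Bns'")
    a, unit_a, b, unit_b = m.groups()
    a, b = float(a), float(b)
    if unit_a or unit_b:
        start = int(np.ceil(a / dt_ns))
        stop = int(np.floor(b / dt_ns))
    else:
        start, stop = int(a), int(b)
    if start > stop:
        raise ConfigError(f"window {window!r} is empty after frame mapping")
    if stop >= n_frames:
        raise InputError(f"window {window!r} extends past the last frame ({n_frames - 1})")
    return start, stop


def read_system(topology: str | Path, trajectory: str | Path | None = None,
                window: str | None = None, dt_ns: float = 1.0
                ) -> tuple[mda.Universe, tuple[int, int] | None]:
    """Load topology + trajectory and resolve the frame window.

    Raises :class:`InputError` with the offending path for unreadable or
    mismatched files (e.g. trajectory/topology atom-count mismatch).
    """
    for p in (topology, trajectory):
        if p is not None and not Path(p).is_file():
            raise InputError(f"cannot read file: {p}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = (mda.Universe(str(topology)) if trajectory is None
                 else mda.Universe(str(topology), str(trajectory)))
    except Exception as exc:  # MDAnalysis raises assorted types here
        raise InputError(f"failed to parse {topology} / {trajectory}: {exc}") from exc
    return u, parse_window(window, dt_ns, len(u.trajectory))


def topology_from_universe(u: mda.Universe, chain_roles: dict[str, str]) -> ComplexTopology:
    """Derive a :class:`ComplexTopology` from the structure's own residue
    names; residue numbering is taken verbatim from the input."""
    from .topology import THREE_TO_ONE
    chains = []
    for chain_id, role in sorted(chain_roles.items()):
        res = u.select_atoms(f"chainID {chain_id}").residues
        if len(res) == 0:
            raise ConfigError(f"configured chain {chain_id!r} has no residues in the input")
        seq = "".join(THREE_TO_ONE.get(rn, "A") for rn in res.resnames)
        chains.append(ChainDef(chain_id, role, seq, first_resid=int(res.resids.min())))
    return ComplexTopology(chains=tuple(chains))


def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6f")


def _write_matrix(cmap: ContactMap, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        cmap.as_dataframe().to_csv(fh, lineterminator="\n", float_format="%.6f")


def run_all(config: AnalysisConfig) -> RunReport:
    """Run the full analysis over every configured system."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"tdanalyze {__version__} config={config.content_hash()} seed={config.seed}"
    notices: list[str] = []
    systems_report: dict = {}
    persistent_maps: dict = {}
    occupancy_frames = []

    roles_lower = {c: r.lower() for c, r in config.chain_roles.items()}
    receptor_chain = next(c for c, r in roles_lower.items() if r in ("trem2", "receptor"))
    adaptor_ids = tuple(sorted(c for c, r in roles_lower.items() if r in ("dap12", "adaptor")))

    topo = None
    for spec in config.systems:
        u, window = read_system(spec.topology, spec.trajectory, spec.window, spec.dt_ns)
        topo = topology_from_universe(u, config.chain_roles)
        files: dict[str, str] = {}

        ks = kink_series(u, config.kink_vectors, bin_width=config.bin_width)
        kink_df = pd.DataFrame({
            "frame": np.arange(ks.n_frames),
            "time_ns": np.arange(ks.n_frames) * spec.dt_ns,
            "angle_deg": ks.angles,
        })
        p = out / f"kink_{spec.name}.csv"
        _write_csv(kink_df, p, prov)
        files["kink"] = p.name

        for adaptor in adaptor_ids:
            cmap = contact_map(u, (receptor_chain, adaptor), level="c_alpha",
                               cutoff=config.ca_cutoff, window=window)
            p = out / f"contacts_ca_{spec.name}_{adaptor}.csv"
            _write_matrix(cmap, p, prov)
            files[f"contacts_ca_{adaptor}"] = p.name

            aa = contact_map(u, (receptor_chain, adaptor), level="all_atom",
                             cutoff=config.aa_cutoff, window=window)
            persistent = persistence_filter(aa, config.persistence_threshold)
            persistent_maps[(spec.name, adaptor)] = persistent
            p = out / f"contacts_aa_persistent_{spec.name}_{adaptor}.csv"
            _write_matrix(persistent, p, prov)
            files[f"contacts_aa_persistent_{adaptor}"] = p.name

        registry = default_registry(adaptor_chains=adaptor_ids, donor_chain=receptor_chain)
        occ = occupancy_table(u, registry, config.hbond_criteria, system=spec.name)
        occupancy_frames.append(occ)
        occ_out = occ.copy()
        occ_out["occupancy"] = [round_half_up(x, 2) for x in occ_out["occupancy"]]
        p = out / f"occupancy_{spec.name}.csv"
        _write_csv(occ_out, p, prov)
        files["occupancy"] = p.name

        total, per_label = hbond_count_series(u, registry, config.hbond_criteria)
        counts_df = pd.DataFrame({"frame": np.arange(len(total)), "n_hbonds": total})
        counts_df = pd.concat([counts_df, per_label], axis=1)
        p = out / f"hbond_counts_{spec.name}.csv"
        _write_csv(counts_df, p, prov)
        files["hbond_counts"] = p.name

        systems_report[spec.name] = {
            "n_frames": int(len(u.trajectory)),
            "window_frames": list(window) if window else None,
            "kink": {"mean": ks.mean, "sem": ks.mean_error, "mode": ks.mode},
            "files": files,
        }

    occupancies = pd.concat(occupancy_frames, ignore_index=True)
    consensus_report = None
    if len(config.systems) >= 3:
        consensus = consensus_merge(persistent_maps, min_count=config.consensus_min_count)
        p = out / "consensus.csv"
        _write_csv(consensus.counts, p, prov)
        consensus_report = {
            "n_maps": consensus.n_maps, "min_count": consensus.min_count,
            "retained": sorted([list(t) for t in consensus.retained_pairs]),
            "file": p.name,
        }
        if consensus.retained_pairs:
            classes = classify_interactions(consensus, topo, occupancies,
                                            receptor_chain=receptor_chain)
            classes = classes.assign(classes=classes["classes"].map(lambda t: "+".join(t)))
            p = out / "interactions.csv"
            _write_csv(classes, p, prov)
            consensus_report["interactions_file"] = p.name
        else:
            notices.append("consensus set empty; interaction classification skipped")
    else:
        notices.append(
            f"consensus skipped: {len(config.systems)} system(s) configured, 3 required")

    report = RunReport(
        out_dir=out,
        provenance={"package": "tdanalyze", "version": __version__,
                    "mdanalysis": mda.__version__, "config_hash": config.content_hash(),
                    "seed": config.seed},
        systems=systems_report, consensus=consensus_report, notices=notices)
    (out / "report.json").write_text(report.to_json())
    return report
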