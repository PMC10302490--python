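"""Run configuration: YAML schemas for CG representations and calibration runs.

A *representation file* declares the lipids of a training set at bead
resolution — bead names/types, connectivity, optional atom mapping — plus
which angle types are pinned at 180° and the parameter search bounds.
Angles are always enumerated as all connected bead triples, mirroring how
bond and angle types are defined as all connected pairs and triplets of
beads.

A *run file* declares the training systems (lipid, temperature, phase,
experimental APL/D_HH targets), the loss weights, optimizer settings and
the backend.  Defaults: w1=10, w2=50, epsilon=1.5, stale limit 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .loss import LossWeights
from .optimizer import OptimizerConfig
from .topology import (
    DEFAULT_ANGLE_DEG_BOUNDS,
    DEFAULT_ANGLE_FORCE_BOUNDS,
    DEFAULT_BOND_FORCE_BOUNDS,
    DEFAULT_BOND_LENGTH_BOUNDS,
    BeadSpec,
    BuildingBlockLibrary,
    LipidTopology,
    classify_terms,
)

__all__ = ["ConfigError", "Representation", "RunConfig", "load_representation",
           "load_run_config"]

DATA_DIR = Path(__file__).parent / "data"


class ConfigError(ValueError):
    """Schema violation or missing file in a run configuration."""


@dataclass
class Representation:
    name: str
    topologies: tuple[LipidTopology, ...]
    fixed_angle_keys: tuple[tuple[str, ...], ...] = ()
    bounds: dict = field(default_factory=dict)

    def build_library(self) -> BuildingBlockLibrary:
        lib = classify_terms(self.topologies, fixed_angle_keys=self.fixed_angle_keys)
        bl = tuple(self.bounds.get("bond_length", DEFAULT_BOND_LENGTH_BOUNDS))
        bk = tuple(self.bounds.get("bond_force", DEFAULT_BOND_FORCE_BOUNDS))
        ae = tuple(self.bounds.get("angle_deg", DEFAULT_ANGLE_DEG_BOUNDS))
        ak = tuple(self.bounds.get("angle_force", DEFAULT_ANGLE_FORCE_BOUNDS))
        for block in lib:
            if block.kind == "bond":
                block.equilibrium_bounds, block.force_bounds = bl, bk
            else:
                block.equilibrium_bounds, block.force_bounds = ae, ak
        return lib


def _parse_lipid(name: str, spec: dict) -> LipidTopology:
    try:
        raw_beads = spec["beads"]
    except KeyError:
        raise ConfigError(f"lipid {name}: missing 'beads'") from None
    beads = []
    offset = 0
    for i, b in enumerate(raw_beads):
        if isinstance(b, str):
            b = {"type": b}
        atoms = b.get("atoms")
        if atoms is None:
            atoms = [offset]
            offset += 1
        beads.append(
            BeadSpec(
                name=b.get("name", f"B{i + 1}"),
                bead_type=b["type"],
                mapped_atoms=tuple(atoms),
            )
        )
    bonds = spec.get("bonds")
    angles = spec.get("angles")
    try:
        if angles is not None:
            if bonds is None:
                bonds = [(i, i + 1) for i in range(len(beads) - 1)]
            return LipidTopology(
                name, tuple(beads),
                tuple(tuple(b) for b in bonds),
                tuple(tuple(a) for a in angles),
            )
        return LipidTopology.from_chain(name, beads, bonds)
    except ValueError as exc:
        raise ConfigError(f"lipid {name}: {exc}") from exc


def load_representation(source) -> Representation:
    """Load a representation from a YAML path, a bundled name, or a dict."""
    if isinstance(source, dict):
        doc = source
        name = doc.get("name", "unnamed")
    else:
        path = Path(source)
        if not path.exists():
            bundled = DATA_DIR / f"{source}.yaml"
            if bundled.exists():
                path = bundled
            else:
                raise ConfigError(f"representation file not found: {source}")
        doc = yaml.safe_load(path.read_text())
        name = doc.get("name", path.stem)
    if "lipids" not in doc or not doc["lipids"]:
        raise ConfigError("representation must declare at least one lipid")
    topologies = tuple(
        _parse_lipid(lipid, spec) for lipid, spec in doc["lipids"].items()
    )
    fixed = tuple(tuple(k) for k in doc.get("fixed_angles", []))
    return Representation(
        name=name,
        topologies=topologies,
        fixed_angle_keys=fixed,
        bounds=doc.get("bounds", {}),
    )


@dataclass
class SystemSpec:
    lipid: str
    temperature: float
    phase: str = "liquid"
    exp_apl: float = 0.0
    exp_dhh: float = 0.0
    n_lipids: int = 128


@dataclass
class BackendSpec:
    type: str = "surrogate"
    seed: int = 12345
    noise_frac: float = 0.003
    n_samples: int = 2000
    reference_samples: int = 20000
    command_templates: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    representation: Representation
    systems: list[SystemSpec]
    weights: LossWeights = field(default_factory=LossWeights)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    backend: BackendSpec = field(default_factory=BackendSpec)
    output_dir: str = "cgcalib_run"


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"run config not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError("run config must be a YAML mapping")
    for key in ("representation", "systems"):
        if key not in doc:
            raise ConfigError(f"run config missing '{key}'")

    rep_source = doc["representation"]
    if isinstance(rep_source, str) and not Path(rep_source).is_absolute():
        local = path.parent / rep_source
        if local.exists():
            rep_source = local
    representation = load_representation(rep_source)
    lipids = {t.lipid_name for t in representation.topologies}

    systems = []
    for s in doc["systems"]:
        try:
            spec = SystemSpec(
                lipid=s["lipid"],
                temperature=float(s["temperature"]),
                phase=s.get("phase", "liquid"),
                exp_apl=float(s.get("exp_apl", 0.0)),
                exp_dhh=float(s.get("exp_dhh", 0.0)),
                n_lipids=int(s.get("n_lipids", 128)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad system entry {s!r}: {exc}") from exc
        if spec.lipid not in lipids:
            raise ConfigError(f"system lipid {spec.lipid!r} not in representation")
        if spec.phase not in ("liquid", "gel"):
            raise ConfigError(f"bad phase {spec.phase!r}")
        systems.append(spec)
    if not systems:
        raise ConfigError("run config declares no training systems")

    w = doc.get("weights", {})
    weights = LossWeights(
        w1=float(w.get("w1", 10.0)),
        w2=float(w.get("w2", 50.0)),
        epsilon=float(w.get("epsilon", 1.5)),
    )
    o = doc.get("optimizer", {})
    optimizer = OptimizerConfig(
        swarm_size=o.get("swarm_size"),
        max_iterations=int(o.get("max_iterations", 500)),
        stale_limit=int(o.get("stale_limit", 10)),
        mode=o.get("mode", "fst"),
        seed=int(o.get("seed", 0)),
    )
    if optimizer.mode not in ("fst", "plain"):
        raise ConfigError(f"bad optimizer mode {optimizer.mode!r}")
    b = doc.get("backend", {})
    backend = BackendSpec(
        type=b.get("type", "surrogate"),
        seed=int(b.get("seed", 12345)),
        noise_frac=float(b.get("noise_frac", 0.003)),
        n_samples=int(b.get("n_samples", 2000)),
        reference_samples=int(b.get("reference_samples", 20000)),
        command_templates=list(b.get("command_templates", [])),
    )
    if backend.type not in ("surrogate", "md"):
        raise ConfigError(f"bad backend type {backend.type!r}")
    return RunConfig(
        representation=representation,
        systems=systems,
        weights=weights,
        optimizer=optimizer,
        backend=backend,
        output_dir=doc.get("output_dir", "cgcalib_run"),
    )
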