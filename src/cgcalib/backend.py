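"""Simulation backends: the contract an MD engine adapter must satisfy,
plus a deterministic surrogate that makes end-to-end calibration testable
without any MD engine.

The surrogate emulates what an equilibrium CG bilayer simulation would
report for a candidate parameter set:

* bond samples are drawn from a Gaussian centered on the candidate
  equilibrium with variance RT/k — the Boltzmann statistics of a harmonic
  term at the system temperature (no r^2 Jacobian; adequate for stiff
  bonds and it keeps the planted optimum exact);
* angle samples likewise, truncated to [0°, 180°];
* APL and D_HH respond linearly to normalized parameter errors relative
  to a hidden ground truth: APL = exp_apl * (1 + sum_i c_i * delta_i) +
  noise, where delta_i = (p_i - p_true_i) / (hi_i - lo_i), and the sparse
  response coefficients c_i are drawn once per ground truth.

At the true parameters the expected observables equal the experimental
targets and every expected distribution distance vanishes, so the full
loss has a planted optimum at the truth.  Results are deterministic
given the ground-truth seed and the candidate parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import mapping
from .mapping import GeomDistribution, histogram
from .topology import (
    BuildingBlockLibrary,
    LipidTopology,
    ParameterVector,
    canonical_key,
    decode,
    encode,
    parameter_bounds,
    write_itp,
)

__all__ = [
    "KB_KJ_PER_MOL_K",
    "TrainingSystem",
    "SimulationResult",
    "SurrogateGroundTruth",
    "surrogate_simulate",
    "make_synthetic_references",
    "MDBackend",
]

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K


@dataclass
class TrainingSystem:
    """One (lipid, temperature) bilayer of the training set."""

    lipid_name: str
    temperature: float                      # K
    phase_label: str = "liquid"             # "liquid" | "gel"
    exp_apl: float = 0.0                    # Å²
    exp_dhh: float = 0.0                    # Å
    references: dict[tuple[str, tuple[str, ...]], GeomDistribution] = field(
        default_factory=dict
    )
    n_lipids: int = 128

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.phase_label not in ("liquid", "gel"):
            raise ValueError(f"bad phase label {self.phase_label!r}")

    @property
    def name(self) -> str:
        return f"{self.lipid_name}@{self.temperature:g}K"


@dataclass
class SimulationResult:
    success: bool
    apl: float = np.nan                     # Å²
    dhh: float = np.nan                     # Å
    distributions: dict[tuple[str, tuple[str, ...]], GeomDistribution] = field(
        default_factory=dict
    )
    failure_reason: str = ""

    def __post_init__(self):
        if self.success and not (
            np.isfinite(self.apl) and np.isfinite(self.dhh) and self.distributions
        ):
            raise ValueError("successful result must carry finite observables "
                             "and distributions")


@dataclass
class SurrogateGroundTruth:
    """Hidden true parameters plus the linear observable response model."""

    library: BuildingBlockLibrary           # true parameters
    topologies: tuple[LipidTopology, ...]
    seed: int = 12345
    noise_frac: float = 0.003               # sd of observable noise, fraction of target
    n_samples: int = 2000                   # samples per block per evaluation
    response: dict[str, np.ndarray] = field(default_factory=dict)  # per system

    def __post_init__(self):
        self.topologies = tuple(self.topologies)

    def response_for(self, system_name: str) -> np.ndarray:
        """Sparse response coefficients (2, n_free) for APL and D_HH,
        drawn once per system with magnitudes in ±[0.01, 0.05]."""
        if system_name not in self.response:
            n = len(encode(self.library))
            h = int.from_bytes(
                hashlib.sha256(f"{self.seed}:{system_name}".encode()).digest()[:4],
                "big",
            )
            rng = np.random.default_rng(h)
            coeff = rng.uniform(0.01, 0.05, size=(2, n))
            coeff *= rng.choice([-1.0, 1.0], size=(2, n))
            coeff *= rng.random(size=(2, n)) < 0.6   # sparsity
            self.response[system_name] = coeff
        return self.response[system_name]


def _blocks_of_system(truth: SurrogateGroundTruth, system: TrainingSystem):
    """Building blocks instantiated by the system's lipid, with counts."""
    topo = next(
        t for t in truth.topologies if t.lipid_name == system.lipid_name
    )
    counts: dict[tuple[str, tuple[str, ...]], int] = {}
    for i, j in topo.bonds:
        k = ("bond", canonical_key(topo.bead_types((i, j))))
        counts[k] = counts.get(k, 0) + 1
    for i, j, kk in topo.angles:
        k = ("angle", canonical_key(topo.bead_types((i, j, kk))))
        counts[k] = counts.get(k, 0) + 1
    return counts


def _eval_rng(truth: SurrogateGroundTruth, system: TrainingSystem,
              tag: str = "") -> np.random.Generator:
    """Deterministic RNG keyed on the ground truth and system only.

    Every candidate evaluation reuses the same underlying random draws
    (common random numbers), which keeps the surrogate loss landscape a
    smooth deterministic function of the parameters while still carrying
    realistic finite-sampling noise relative to the references."""
    digest = hashlib.sha256(f"{truth.seed}:{system.name}:{tag}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def _draw_block_samples(
    rng: np.random.Generator, kind: str, equilibrium: float,
    force_constant: float, temperature: float, n: int,
) -> np.ndarray:
    rt = KB_KJ_PER_MOL_K * temperature
    z = rng.standard_normal(n)
    if kind == "bond":
        sigma_nm = np.sqrt(rt / force_constant)
        return (equilibrium + sigma_nm * z) * 10.0  # Å
    sigma_deg = np.degrees(np.sqrt(rt / force_constant))
    # reflect at the domain walls (angles live in [0, 180])
    samples = np.abs(equilibrium + sigma_deg * z)
    samples = 180.0 - np.abs(180.0 - samples)
    return np.clip(samples, 0.0, 180.0 - 1e-9)


def surrogate_simulate(
    params: ParameterVector,
    system: TrainingSystem,
    truth: SurrogateGroundTruth,
    n_samples: int | None = None,
    noise_frac: float | None = None,
) -> SimulationResult:
    """Emulate one CG bilayer simulation for a candidate parameter set."""
    try:
        candidate = decode(params, truth.library)
    except Exception as exc:  # undecodable -> crashed run
        return SimulationResult(False, failure_reason=f"decode failed: {exc}")
    bounds = parameter_bounds(truth.library)
    if np.any(params.values < bounds[:, 0] - 1e-9) or np.any(
        params.values > bounds[:, 1] + 1e-9
    ):
        return SimulationResult(False, failure_reason="parameters outside physical bounds")

    n = n_samples if n_samples is not None else truth.n_samples
    noise = noise_frac if noise_frac is not None else truth.noise_frac

    distributions = {}
    for (kind, key), count in _blocks_of_system(truth, system).items():
        blk = candidate.blocks[(kind, key)]
        rng = _eval_rng(truth, system, f"{kind}:{'-'.join(key)}")
        samples = _draw_block_samples(
            rng, kind, blk.equilibrium, blk.force_constant, system.temperature,
            n * count,
        )
        if kind == "bond" and samples.max() >= mapping.BOND_BIN_EDGES[-1]:
            return SimulationResult(
                False, failure_reason=f"bond {key} samples beyond grid (unstable)"
            )
        distributions[(kind, key)] = histogram(samples, kind)

    true_vals = encode(truth.library).values
    span = bounds[:, 1] - bounds[:, 0]
    delta = (params.values - true_vals) / span
    coeff = truth.response_for(system.name)
    apl = system.exp_apl * (1.0 + float(coeff[0] @ delta))
    dhh = system.exp_dhh * (1.0 + float(coeff[1] @ delta))
    if noise > 0:
        obs_rng = _eval_rng(truth, system, "observables")
        apl += system.exp_apl * noise * obs_rng.standard_normal()
        dhh += system.exp_dhh * noise * obs_rng.standard_normal()
    if apl <= 0 or dhh <= 0:
        return SimulationResult(False, failure_reason="bilayer destroyed")
    return SimulationResult(True, apl=apl, dhh=dhh, distributions=distributions)


def make_synthetic_references(
    truth: SurrogateGroundTruth,
    systems,
    n_samples: int = 20000,
) -> list[TrainingSystem]:
    """Fill each system's reference distributions and pseudo-experimental
    targets from the surrogate at the true parameters (noise-free means,
    large sample count).  Regeneration with the same ground-truth seed is
    bit-identical."""
    params = encode(truth.library)
    out = []
    for system in systems:
        sys_with_targets = TrainingSystem(
            lipid_name=system.lipid_name,
            temperature=system.temperature,
            phase_label=system.phase_label,
            exp_apl=system.exp_apl if system.exp_apl > 0 else 1.0,
            exp_dhh=system.exp_dhh if system.exp_dhh > 0 else 1.0,
            n_lipids=system.n_lipids,
        )
        result = surrogate_simulate(
            params, sys_with_targets, truth, n_samples=n_samples, noise_frac=0.0
        )
        if not result.success:
            raise RuntimeError(
                f"reference generation failed for {system.name}: {result.failure_reason}"
            )
        out.append(
            TrainingSystem(
                lipid_name=system.lipid_name,
                temperature=system.temperature,
                phase_label=system.phase_label,
                exp_apl=system.exp_apl if system.exp_apl > 0 else result.apl,
                exp_dhh=system.exp_dhh if system.exp_dhh > 0 else result.dhh,
                references=result.distributions,
                n_lipids=system.n_lipids,
            )
        )
    return out


class MDBackend:
    """Adapter contract for a real MD engine (e.g. GROMACS).

    The backend stages topology/coordinate inputs in a per-evaluation
    working directory, invokes user-supplied command templates, and
    parses the produced trajectory through the mapping and observables
    modules.  This class implements staging, command templating, a
    dry-run mode and failure mapping; it never ships or wraps a specific
    engine.
    """

    def __init__(self, command_templates: list[str], topologies,
                 dry_run: bool = False):
        if not command_templates:
            raise ValueError("configuration error: no command templates")
        self.command_templates = list(command_templates)
        self.topologies = tuple(topologies)
        self.dry_run = dry_run

    def stage(self, params: ParameterVector, library: BuildingBlockLibrary,
              system: TrainingSystem, workdir) -> list[str]:
        from pathlib import Path

        wd = Path(workdir)
        wd.mkdir(parents=True, exist_ok=True)
        candidate = decode(params, library)
        staged = []
        for topo in self.topologies:
            if topo.lipid_name != system.lipid_name:
                continue
            path = wd / f"{topo.lipid_name}.itp"
            path.write_text(write_itp(candidate, topo))
            staged.append(str(path))
        commands = [
            t.format(workdir=str(wd), lipid=system.lipid_name,
                     temperature=system.temperature)
            for t in self.command_templates
        ]
        (wd / "MANIFEST.txt").write_text(
            "\n".join(["# staged inputs"] + staged + ["# commands"] + commands) + "\n"
        )
        return commands

    def run(self, params: ParameterVector, library: BuildingBlockLibrary,
            system: TrainingSystem, workdir) -> SimulationResult:
        import subprocess

        commands = self.stage(params, library, system, workdir)
        if self.dry_run:
            return SimulationResult(False, failure_reason="dry run: not executed")
        for cmd in commands:
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                return SimulationResult(
                    False,
                    failure_reason=f"command failed ({proc.returncode}): {cmd}",
                )
        return self.parse_output(system, workdir)

    def parse_output(self, system: TrainingSystem, workdir) -> SimulationResult:
        raise NotImplementedError(
            "engine-specific trajectory parsing must be supplied by the adapter"
        )
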