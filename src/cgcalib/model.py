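"""Model/Results surface for bonded-parameter calibration.

:class:`BondedCalibration` holds everything a calibration needs — the
building-block library derived from a CG representation, the training
systems with their reference distributions and experimental targets, the
loss weights and a simulation backend — and exposes ``evaluate`` for a
single loss decomposition and ``fit`` for the full swarm optimization.
``fit`` returns a :class:`CalibrationResult` carrying the best parameter
vector, the decoded library, the loss decomposition at the optimum, the
per-iteration history as a DataFrame, and ``summary()`` /
``plot_convergence()`` for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import optimizer as opt
from .backend import (
    SurrogateGroundTruth,
    TrainingSystem,
    make_synthetic_references,
    surrogate_simulate,
)
from .config import RunConfig
from .loss import LossReport, LossWeights, emd_1d
from .observables import percent_deviation
from .topology import (
    BuildingBlockLibrary,
    ParameterVector,
    canonical_key,
    decode,
    encode,
    parameter_bounds,
    write_itp,
)

__all__ = ["BondedCalibration", "CalibrationResult"]


class BondedCalibration:
    """Calibration problem for the bonded parameters of a lipid representation.

    Parameters
    ----------
    library : BuildingBlockLibrary
        Blocks whose free parameters are optimized; their current values
        only seed the layout, not the search.
    topologies : sequence of LipidTopology
        The lipids of the representation.
    systems : sequence of TrainingSystem
        Training systems with experimental targets and reference
        bond/angle distributions.
    simulate : callable(params, system) -> SimulationResult
        The simulation backend.
    weights : LossWeights
    """

    def __init__(self, library, topologies, systems, simulate,
                 weights: LossWeights | None = None):
        self.library = library
        self.topologies = tuple(topologies)
        self.systems = list(systems)
        self.simulate = simulate
        self.weights = weights or LossWeights()
        if not self.systems:
            raise ValueError("need at least one training system")
        for s in self.systems:
            if not s.references:
                raise ValueError(f"system {s.name} has no reference distributions")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_config(cls, config: RunConfig) -> "BondedCalibration":
        """Build the calibration a run config describes.

        With the surrogate backend, a hidden ground truth is drawn from
        the backend seed (equilibria and force constants uniform within
        the block bounds) and the systems' reference distributions and
        any missing experimental targets are generated from it.
        """
        library = config.representation.build_library()
        topologies = config.representation.topologies
        if config.backend.type != "surrogate":
            raise NotImplementedError(
                "from_config supports the surrogate backend; wire an MDBackend "
                "adapter through the constructor for engine-driven runs"
            )
        truth_lib = _random_truth(library, config.backend.seed)
        truth = SurrogateGroundTruth(
            truth_lib, topologies, seed=config.backend.seed,
            noise_frac=config.backend.noise_frac,
            n_samples=config.backend.n_samples,
        )
        bare = [
            TrainingSystem(
                lipid_name=s.lipid, temperature=s.temperature, phase_label=s.phase,
                exp_apl=s.exp_apl, exp_dhh=s.exp_dhh, n_lipids=s.n_lipids,
            )
            for s in config.systems
        ]
        systems = make_synthetic_references(
            truth, bare, n_samples=config.backend.reference_samples
        )
        model = cls(
            library, topologies, systems,
            simulate=lambda p, s: surrogate_simulate(p, s, truth),
            weights=config.weights,
        )
        model.truth = truth
        return model

    @classmethod
    def from_surrogate_truth(cls, truth: SurrogateGroundTruth, systems,
                             weights: LossWeights | None = None,
                             reference_samples: int = 20000) -> "BondedCalibration":
        """Planted-optimum calibration: references generated at the truth."""
        systems = make_synthetic_references(truth, systems,
                                            n_samples=reference_samples)
        model = cls(
            truth.library.copy(), truth.topologies, systems,
            simulate=lambda p, s: surrogate_simulate(p, s, truth),
            weights=weights,
        )
        model.truth = truth
        return model

    # -- evaluation ---------------------------------------------------

    @property
    def bounds(self) -> np.ndarray:
        return parameter_bounds(self.library)

    @property
    def n_free_parameters(self) -> int:
        return len(encode(self.library))

    def _instance_counts(self, system: TrainingSystem) -> dict:
        topo = next(t for t in self.topologies if t.lipid_name == system.lipid_name)
        counts: dict = {}
        for i, j in topo.bonds:
            k = ("bond", canonical_key(topo.bead_types((i, j))))
            counts[k] = counts.get(k, 0) + 1
        for i, j, kk in topo.angles:
            k = ("angle", canonical_key(topo.bead_types((i, j, kk))))
            counts[k] = counts.get(k, 0) + 1
        return counts

    def evaluate(self, params: ParameterVector) -> LossReport:
        """One full loss decomposition for a candidate parameter vector.

        Every system is simulated; per-block Wasserstein distances are
        pooled across systems weighted by instance counts.  A failed
        simulation marks the system in the report and the total loss is
        +inf (the optimizer treats it as a crashed evaluation).
        """
        apl_dev: dict[str, float] = {}
        dhh_dev: dict[str, float] = {}
        block_distances: dict = {}
        failed = []
        for system in self.systems:
            result = self.simulate(params, system)
            if not result.success:
                failed.append(system.name)
                continue
            apl_dev[system.name] = percent_deviation(result.apl, system.exp_apl)
            dhh_dev[system.name] = percent_deviation(result.dhh, system.exp_dhh)
            counts = self._instance_counts(system)
            for key, dist in result.distributions.items():
                ref = system.references.get(key)
                if ref is None:
                    continue
                d = emd_1d(dist, ref)
                block_distances.setdefault(key, []).extend([d] * counts.get(key, 1))
        if failed and not apl_dev:
            report = LossReport(
                weights=self.weights, apl_deviations={}, dhh_deviations={},
                apl_global=np.inf, dhh_global=np.inf, per_block={}, otb=np.inf,
                total=np.inf, failed_systems=failed,
            )
            return report
        report = LossReport.from_components(
            self.weights, apl_dev, dhh_dev, block_distances, failed_systems=failed,
        )
        if failed:
            report.total = np.inf
        return report

    def loss(self, values: np.ndarray) -> float:
        return self.evaluate(self.make_params(values)).total

    def make_params(self, values: np.ndarray) -> ParameterVector:
        return ParameterVector(np.asarray(values, dtype=float),
                               encode(self.library).layout)

    def seed_vector(self) -> np.ndarray:
        """First-particle prior: equilibrium values from the means of the
        reference distributions (AA-mapped knowledge), force constants at
        the midpoints of their configured ranges."""
        layout = encode(self.library).layout
        bounds = self.bounds
        ref_means: dict = {}
        weights_acc: dict = {}
        for system in self.systems:
            counts = self._instance_counts(system)
            for key, ref in system.references.items():
                w = counts.get(key, 1)
                ref_means[key] = ref_means.get(key, 0.0) + w * ref.mean()
                weights_acc[key] = weights_acc.get(key, 0) + w
        seed = np.empty(len(layout))
        for idx, (kind, key, role) in enumerate(layout):
            if role == "equilibrium" and (kind, key) in ref_means:
                mean = ref_means[(kind, key)] / weights_acc[(kind, key)]
                seed[idx] = mean / 10.0 if kind == "bond" else mean  # Å -> nm
            else:
                seed[idx] = 0.5 * (bounds[idx, 0] + bounds[idx, 1])
        return np.clip(seed, bounds[:, 0], bounds[:, 1])

    # -- fitting ------------------------------------------------------

    def fit(self, optimizer_config: opt.OptimizerConfig | None = None,
            callback=None) -> "CalibrationResult":
        config = optimizer_config or opt.OptimizerConfig()
        eval_log: list[dict] = []

        def objective(values: np.ndarray) -> float:
            report = self.evaluate(self.make_params(values))
            eval_log.append(
                {
                    "total": report.total,
                    "apl_global": report.apl_global,
                    "dhh_global": report.dhh_global,
                    "otb": report.otb,
                    "n_failed": len(report.failed_systems),
                }
            )
            return report.total

        best, best_loss, history, reason = opt.optimize(
            objective, self.bounds, config,
            seed_vector=self.seed_vector(), callback=callback,
        )
        params = self.make_params(best)
        n_particles = len(history.iterations[0]["losses"])
        rows = []
        for it in history.iterations:
            for pi, loss_value in enumerate(it["losses"]):
                entry = eval_log[(it["iteration"] - 1) * n_particles + pi]
                rows.append(
                    {
                        "iteration": it["iteration"],
                        "particle": pi,
                        "loss": loss_value,
                        "apl_global": entry["apl_global"],
                        "dhh_global": entry["dhh_global"],
                        "otb": entry["otb"],
                        "best_loss": it["best_loss"],
                    }
                )
        return CalibrationResult(
            model=self,
            params=params,
            library=decode(params, self.library),
            loss=best_loss,
            report=self.evaluate(params),
            history=pd.DataFrame(rows),
            converged=reason == "stale_iterations",
            convergence_reason=reason,
            optimizer_config=config,
        )


def _random_truth(library: BuildingBlockLibrary, seed: int) -> BuildingBlockLibrary:
    """Hidden true parameters drawn uniformly within the central half of
    each block's bounds (kept off the walls so the optimum is interior)."""
    rng = np.random.default_rng(seed)
    truth = library.copy()
    for block in truth:
        for role, (lo, hi) in (
            ("equilibrium", block.equilibrium_bounds),
            ("force_constant", block.force_bounds),
        ):
            if role == "equilibrium" and block.equilibrium_fixed:
                continue
            span = hi - lo
            setattr(block, role, float(rng.uniform(lo + 0.25 * span, hi - 0.25 * span)))
    return truth


@dataclass
class CalibrationResult:
    """Fit output: optimal parameters, diagnostics and reporting helpers."""

    model: BondedCalibration
    params: ParameterVector
    library: BuildingBlockLibrary
    loss: float
    report: LossReport
    history: pd.DataFrame
    converged: bool
    convergence_reason: str
    optimizer_config: opt.OptimizerConfig
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Bonded-parameter calibration",
            "=" * 60,
            f"free parameters        : {self.model.n_free_parameters}",
            f"training systems       : {len(self.model.systems)}",
            f"optimizer mode         : {self.optimizer_config.mode}",
            f"iterations run         : {int(self.history['iteration'].max())}",
            f"converged              : {self.converged} ({self.convergence_reason})",
            f"best loss              : {self.loss:.4f}",
            f"  top-down dAPL_global : {self.report.apl_global:.4f}",
            f"  top-down dDHH_global : {self.report.dhh_global:.4f}",
            f"  bottom-up OT-B_global: {self.report.otb:.4f}",
            "",
            "per-system % deviations (APL / D_HH):",
        ]
        for name in self.report.apl_deviations:
            lines.append(
                f"  {name:<20s} {self.report.apl_deviations[name]:+7.2f}%  /"
                f"  {self.report.dhh_deviations[name]:+7.2f}%"
            )
        lines += ["", "building blocks (equilibrium, force constant):"]
        for block in sorted(self.library, key=lambda b: (b.kind, b.key)):
            eq_unit = "nm" if block.kind == "bond" else "deg"
            fixed = " [fixed]" if block.equilibrium_fixed else ""
            lines.append(
                f"  {block.kind:<5s} {'-'.join(block.key):<18s} "
                f"{block.equilibrium:8.4g} {eq_unit}{fixed}  "
                f"k={block.force_constant:.5g}"
            )
        return "\n".join(lines)

    def best_loss_curve(self) -> pd.Series:
        return self.history.groupby("iteration")["best_loss"].first()

    def plot_convergence(self, ax=None):
        """Best-so-far global loss (solid) over raw per-particle losses."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        finite = self.history[np.isfinite(self.history["loss"])]
        ax.scatter(finite["iteration"], finite["loss"], s=6, alpha=0.25,
                   color="gray", label="raw evaluations")
        curve = self.best_loss_curve()
        ax.plot(curve.index, curve.values, color="seagreen", lw=2,
                label="global best")
        ax.set_xlabel("swarm iteration")
        ax.set_ylabel("loss")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def write_topologies(self, outdir) -> list[str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for topo in self.model.topologies:
            path = outdir / f"{topo.lipid_name}.itp"
            path.write_text(write_itp(self.library, topo))
            written.append(str(path))
        return written
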