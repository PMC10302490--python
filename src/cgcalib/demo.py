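"""Small planted-truth calibration demo used by the test suite and docs.

Two synthetic PC-like lipids share a four-bead head fragment and differ
in their tails, giving 6 bond types and 6 angle types (no fixed
equilibria), i.e. 24 free parameters — large enough to exercise shared
building blocks across lipids, small enough for desk-scale optimization.
The hidden truth is drawn inside the search bounds; references and
pseudo-experimental targets come from the surrogate at the truth, so the
global optimum of the calibration loss is planted and known.
"""

from __future__ import annotations

import numpy as np

from .backend import SurrogateGroundTruth, TrainingSystem
from .loss import LossWeights
from .model import BondedCalibration
from .topology import BuildingBlock, BuildingBlockLibrary, LipidTopology, classify_terms

__all__ = ["demo_topologies", "make_demo_truth", "make_demo_model"]

# bead-type chains: head Q1-Q5-SN4a(-N4a) fragment + diverging tails
_CHAIN_A = ("Q1", "Q5", "SN4a", "N4a", "C4h")
_CHAIN_B = ("Q1", "Q5", "SN4a", "C1", "C1", "C1")


def demo_topologies() -> tuple[LipidTopology, LipidTopology]:
    lipid_a = LipidTopology.from_chain("DEMA", _CHAIN_A)
    lipid_b = LipidTopology.from_chain("DEMB", _CHAIN_B)
    return lipid_a, lipid_b


def make_demo_truth(seed: int = 7, noise_frac: float = 0.003,
                    n_samples: int = 2000) -> SurrogateGroundTruth:
    """Ground truth with 6 bond + 6 angle blocks (24 free parameters)."""
    topologies = demo_topologies()
    lib = classify_terms(topologies)
    assert len(lib.bonds()) == 6 and len(lib.angles()) == 6
    rng = np.random.default_rng(seed)
    for block in lib:
        if block.kind == "bond":
            block.equilibrium = float(rng.uniform(0.3, 0.55))       # nm
            block.force_constant = float(rng.uniform(1500.0, 6000.0))
        else:
            block.equilibrium = float(rng.uniform(100.0, 165.0))    # deg
            block.force_constant = float(rng.uniform(25.0, 150.0))
    return SurrogateGroundTruth(
        lib, topologies, seed=seed, noise_frac=noise_frac, n_samples=n_samples
    )


def make_demo_systems() -> list[TrainingSystem]:
    return [
        TrainingSystem("DEMA", 303.0, "liquid", exp_apl=63.0, exp_dhh=38.5),
        TrainingSystem("DEMB", 323.0, "liquid", exp_apl=64.5, exp_dhh=38.0),
    ]


def make_demo_model(seed: int = 7, weights: LossWeights | None = None,
                    noise_frac: float = 0.003, n_samples: int = 2000,
                    reference_samples: int = 2000) -> BondedCalibration:
    """Planted-optimum calibration over 24 free parameters, 2 systems."""
    truth = make_demo_truth(seed, noise_frac=noise_frac, n_samples=n_samples)
    return BondedCalibration.from_surrogate_truth(
        truth, make_demo_systems(), weights=weights,
        reference_samples=reference_samples,
    )
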