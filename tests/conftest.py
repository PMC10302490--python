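import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from cgcalib.backend import SurrogateGroundTruth, TrainingSystem
from cgcalib.model import BondedCalibration
from cgcalib.topology import (
    BuildingBlock,
    BuildingBlockLibrary,
    LipidTopology,
    classify_terms,
)


@pytest.fixture
def two_bead_lipid():
    return LipidTopology.from_chain("MINI", ("Q1", "C1"))


@pytest.fixture
def small_library():
    """4 bond + 4 angle blocks shared by two chain lipids (16 free params)."""
    t1 = LipidTopology.from_chain("SMA", ("Q1", "Q5", "SN4a", "C1", "C1"))
    t2 = LipidTopology.from_chain("SMB", ("Q1", "Q5", "SN4a", "C1", "C1", "C1"))
    lib = classify_terms((t1, t2))
    return lib, (t1, t2)


def make_small_truth(seed=7, noise_frac=0.003, n_samples=2000):
    t1 = LipidTopology.from_chain("SMA", ("Q1", "Q5", "SN4a", "C1", "C1"))
    t2 = LipidTopology.from_chain("SMB", ("Q1", "Q5", "SN4a", "C1", "C1", "C1"))
    lib = classify_terms((t1, t2))
    rng = np.random.default_rng(seed)
    for blk in lib:
        if blk.kind == "bond":
            blk.equilibrium = float(rng.uniform(0.3, 0.55))
            blk.force_constant = float(rng.uniform(1500.0, 6000.0))
        else:
            blk.equilibrium = float(rng.uniform(100.0, 165.0))
            blk.force_constant = float(rng.uniform(25.0, 150.0))
    return SurrogateGroundTruth(
        lib, (t1, t2), seed=seed, noise_frac=noise_frac, n_samples=n_samples
    )


def make_small_model(seed=7):
    truth = make_small_truth(seed)
    systems = [
        TrainingSystem("SMA", 303.0, "liquid", exp_apl=63.0, exp_dhh=38.5),
        TrainingSystem("SMB", 323.0, "liquid", exp_apl=64.5, exp_dhh=38.0),
    ]
    return BondedCalibration.from_surrogate_truth(
        truth, systems, reference_samples=2000
    )


@pytest.fixture
def small_model():
    return make_small_model()


@pytest.fixture
def random_histogram_pair():
    from cgcalib.mapping import histogram

    rng = np.random.default_rng(42)

    def make(kind="bond"):
        if kind == "bond":
            a = rng.normal(4.5, 0.4, 500).clip(0.1, 14.5)
            b = rng.normal(5.1, 0.6, 700).clip(0.1, 14.5)
        else:
            a = rng.normal(120.0, 12.0, 500).clip(0, 179.9)
            b = rng.normal(100.0, 20.0, 700).clip(0, 179.9)
        return histogram(a, kind), histogram(b, kind)

    return make
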