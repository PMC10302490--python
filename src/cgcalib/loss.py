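"""Composite calibration loss: hinged top-down deviations plus a
Wasserstein-distance bottom-up term.

The scalar loss minimized during calibration is

    loss = w1 * (dAPL_global + dDHH_global) + OTB_global

where, over the n (lipid, temperature) systems of the training set,

    dAPL_global = (1/n) * sum_i max(0, |d%APL_i| - eps)

and likewise for D_HH: per-system percentage deviations from experiment
are penalized only beyond the tolerated measurement error eps (default
1.5%).  The bottom-up term aggregates, over the B bond types and A angle
types of the representation,

    OTB_global = (1/(B+A)) * [ sum_b w2 * mean_i W1(bond b, instance i)
                               + sum_a mean_j W1(angle a, instance j) ]

with W1 the first Wasserstein (earth mover's) distance between the CG
and AA-mapped distributions, in Å for bonds and degrees for angles.  The
weight w2 (default 50) puts bond and angle mismatches on a common scale:
a 0.4 Å bond distance contributes as much as a 20° angle distance.
With w1 = 10, matching experiment dominates as long as per-type mean
distances stay below 0.2 Å (bonds) and 10° (angles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mapping import GeomDistribution

__all__ = [
    "LossWeights",
    "LossReport",
    "emd_1d",
    "otb_global",
    "topdown_global",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """w1 prioritizes top-down objectives; w2 rescales bond distances (Å)
    onto the angle-degree scale; epsilon is the tolerated measurement
    error on percentage deviations."""

    w1: float = 10.0
    w2: float = 50.0
    epsilon: float = 1.5

    def __post_init__(self):
        if self.w1 <= 0 or self.w2 <= 0 or self.epsilon <= 0:
            raise ValueError("loss weights must be positive")


def emd_1d(p: GeomDistribution, q: GeomDistribution) -> float:
    """First Wasserstein distance between two same-grid histograms.

    Ground metric is the absolute difference of bin centers, so the
    result carries the native units (Å for bonds, degrees for angles).
    For a shared uniform grid, W1 = bin_width * sum |CDF_p - CDF_q|.
    """
    if p.kind != q.kind:
        raise ValueError(f"kind mismatch: {p.kind} vs {q.kind}")
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(
        p.bin_edges, q.bin_edges
    ):
        raise ValueError("histogram grids differ")
    width = p.bin_edges[1] - p.bin_edges[0]
    cdf_diff = np.cumsum(p.masses - q.masses)
    return float(width * np.abs(cdf_diff).sum())


def otb_global(
    block_distances: dict[tuple[str, tuple[str, ...]], list[float] | np.ndarray],
    weights: LossWeights = LossWeights(),
) -> tuple[float, dict]:
    """Aggregate per-instance Wasserstein distances into the bottom-up term.

    ``block_distances`` maps (kind, key) to the distances of every
    instance of that block across the training set (Å for bonds, degrees
    for angles).  Each block contributes its instance mean, bonds scaled
    by w2; the global value is the average over the B + A block types.
    """
    if not block_distances:
        return 0.0, {}
    per_block = {}
    contributions = []
    for (kind, key), dists in block_distances.items():
        d = np.asarray(dists, dtype=float)
        if d.size == 0:
            raise ValueError(f"block {(kind, key)} has no distances")
        mean = float(d.mean())
        scaled = weights.w2 * mean if kind == "bond" else mean
        per_block[(kind, key)] = {"mean_distance": mean, "scaled": scaled}
        contributions.append(scaled)
    return float(np.mean(contributions)), per_block


def topdown_global(
    apl_deviations,
    dhh_deviations,
    weights: LossWeights = LossWeights(),
) -> tuple[float, float]:
    """Hinged means of the per-system percentage deviations.

    Per observable: mean_i max(0, |d%X_i| - epsilon).  Deviations inside
    the epsilon dead zone cost nothing.
    """
    apl = np.asarray(apl_deviations, dtype=float)
    dhh = np.asarray(dhh_deviations, dtype=float)
    if apl.size == 0 or apl.size != dhh.size:
        raise ValueError("need matching, non-empty deviation lists")
    hinge = lambda x: np.maximum(0.0, np.abs(x) - weights.epsilon)  # noqa: E731
    return float(hinge(apl).mean()), float(hinge(dhh).mean())


def total_loss(topdown: tuple[float, float], otb: float, weights: LossWeights) -> float:
    """w1*(dAPL_global + dDHH_global) + OTB_global."""
    d_apl, d_dhh = topdown
    if d_apl < 0 or d_dhh < 0 or otb < 0:
        raise ValueError("loss components must be non-negative")
    return weights.w1 * (d_apl + d_dhh) + otb


@dataclass
class LossReport:
    """Full decomposition of one loss evaluation."""

    weights: LossWeights
    apl_deviations: dict[str, float]   # per system, signed %
    dhh_deviations: dict[str, float]
    apl_global: float
    dhh_global: float
    per_block: dict                    # (kind, key) -> mean/scaled contributions
    otb: float
    total: float
    failed_systems: list[str] = field(default_factory=list)

    @classmethod
    def from_components(
        cls,
        weights: LossWeights,
        apl_deviations: dict[str, float],
        dhh_deviations: dict[str, float],
        block_distances: dict,
        failed_systems=(),
    ) -> "LossReport":
        d_apl, d_dhh = topdown_global(
            list(apl_deviations.values()), list(dhh_deviations.values()), weights
        )
        otb, per_block = otb_global(block_distances, weights)
        return cls(
            weights=weights,
            apl_deviations=dict(apl_deviations),
            dhh_deviations=dict(dhh_deviations),
            apl_global=d_apl,
            dhh_global=d_dhh,
            per_block=per_block,
            otb=otb,
            total=total_loss((d_apl, d_dhh), otb, weights),
            failed_systems=list(failed_systems),
        )

    def to_json(self) -> str:
        payload = {
            "weights": {"w1": self.weights.w1, "w2": self.weights.w2,
                        "epsilon": self.weights.epsilon},
            "apl_percent_deviation": self.apl_deviations,
            "dhh_percent_deviation": self.dhh_deviations,
            "apl_global": self.apl_global,
            "dhh_global": self.dhh_global,
            "otb_per_block": {
                f"{kind}:{'-'.join(key)}": v for (kind, key), v in self.per_block.items()
            },
            "otb_global": self.otb,
            "total_loss": self.total,
            "failed_systems": self.failed_systems,
        }
        return json.dumps(payload, indent=2, sort_keys=True)
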