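"""Gel/liquid phase classification of lipids via neighbor-shuffling.

The LENS descriptor quantifies, per particle and per frame pair
(t, t + stride), the turnover of its neighbor set within a cutoff:

    LENS = |set_t XOR set_{t+stride}| / (|set_t| + |set_{t+stride}|)

which is 0 for a static local environment (gel-like) and 1 for complete
neighbor exchange (liquid-like); two empty sets give 0 by convention.
One representative bead per lipid (by default the first tail bead) is
used for the neighbor lists, with an 11 Å default cutoff between
representative beads.  Lipids are labeled gel or liquid by thresholding
their time-smoothed LENS signal, by default at the midpoint between the
two modes of the pooled LENS histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax
from scipy.spatial import cKDTree

__all__ = [
    "DEFAULT_CUTOFF",
    "NeighborSeries",
    "PhaseLabels",
    "neighbor_series",
    "lens_series",
    "classify_phase",
    "phase_fractions",
]

DEFAULT_CUTOFF = 11.0  # Å between lipid-representative beads


@dataclass
class NeighborSeries:
    """Per sampled frame, per particle: the set of neighbor identities."""

    frames: list[list[frozenset]]
    cutoff: float
    stride: int = 1

    @property
    def n_particles(self) -> int:
        return len(self.frames[0])


@dataclass
class PhaseLabels:
    """Per-lipid, per-frame-pair phase labels plus the parameters used."""

    labels: np.ndarray            # (n_pairs, n_lipids) of "gel"/"liquid"
    lens: np.ndarray              # smoothed per-lipid LENS, same shape
    threshold: float
    cutoff: float
    stride: int

    def gel_mask(self) -> np.ndarray:
        return self.labels == "gel"


def neighbor_series(
    positions: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    box: np.ndarray | None = None,
    stride: int = 1,
) -> NeighborSeries:
    """Neighbor sets within *cutoff* for every sampled frame.

    positions: (n_frames, n_particles, d) in Å; *box* enables periodic
    neighbor searches in orthorhombic boxes.  Self-neighbors are excluded
    and sets are symmetric by construction.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[0] < 2:
        raise ValueError("need (n_frames >= 2, n_particles, dim) positions")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = []
    for f in range(0, positions.shape[0], stride):
        pts = positions[f]
        if box is not None:
            b = np.asarray(box, dtype=float)
            tree = cKDTree(np.mod(pts, b), boxsize=b)
        else:
            tree = cKDTree(pts)
        pairs = tree.query_pairs(cutoff)
        sets: list[set] = [set() for _ in range(pts.shape[0])]
        for i, j in pairs:
            sets[i].add(j)
            sets[j].add(i)
        frames.append([frozenset(s) for s in sets])
    return NeighborSeries(frames, cutoff, stride)


def lens_series(
    positions: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    box: np.ndarray | None = None,
    stride: int = 1,
) -> np.ndarray:
    """LENS descriptor per particle for every consecutive sampled frame pair.

    Returns (n_sampled_frames - 1, n_particles) values in [0, 1].
    """
    series = neighbor_series(positions, cutoff=cutoff, box=box, stride=stride)
    n_frames = len(series.frames)
    n_particles = series.n_particles
    out = np.zeros((n_frames - 1, n_particles))
    for t in range(n_frames - 1):
        now, nxt = series.frames[t], series.frames[t + 1]
        for i in range(n_particles):
            denom = len(now[i]) + len(nxt[i])
            out[t, i] = len(now[i] ^ nxt[i]) / denom if denom else 0.0
    return out


# below this LENS value a unimodal population is considered static (gel)
SINGLE_MODE_THRESHOLD = 0.2


def _bimodal_threshold(values: np.ndarray) -> float:
    """Midpoint between the two dominant modes of the value histogram.

    If the histogram is unimodal (a single-phase system), fall back to a
    fixed threshold so that an all-mobile population is labeled liquid
    and an all-static one gel.
    """
    counts, edges = np.histogram(values, bins=40, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(5)
    smooth = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones_like(counts, dtype=float), kernel, mode="same"
    )
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    peaks = argrelmax(padded)[0] - 1
    peaks = peaks[smooth[peaks] >= 0.1 * smooth.max()]  # ignore stray bins
    if peaks.size >= 2:
        top2 = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
        if top2[1] - top2[0] >= 4:  # genuinely separated modes
            return float(centers[top2].mean())
    return SINGLE_MODE_THRESHOLD


def classify_phase(
    lens: np.ndarray,
    threshold: float | None = None,
    smooth_window: int = 5,
    cutoff: float = DEFAULT_CUTOFF,
    stride: int = 1,
) -> PhaseLabels:
    """Label lipids gel (low LENS) or liquid (high LENS).

    The per-lipid LENS signal is smoothed with a centered moving average
    before thresholding.  With no explicit *threshold*, the midpoint
    between the two modes of the pooled smoothed-LENS histogram is used;
    a degenerate (all-equal) signal yields a single-phase labeling with a
    warning.
    """
    lens = np.asarray(lens, dtype=float)
    if not np.all(np.isfinite(lens)):
        raise ValueError("LENS series must be finite")
    if smooth_window > 1 and lens.shape[0] >= smooth_window:
        kernel = np.ones(smooth_window)
        norm = np.convolve(np.ones(lens.shape[0]), kernel, mode="same")
        smoothed = np.apply_along_axis(
            lambda s: np.convolve(s, kernel, mode="same") / norm, 0, lens
        )
    else:
        smoothed = lens.copy()
    values = smoothed.ravel()
    if threshold is None and np.ptp(values) < 1e-12:
        warnings.warn("degenerate LENS series: labeling everything one phase",
                      stacklevel=2)
        phase = "gel" if values[0] < 0.5 else "liquid"
        labels = np.full(lens.shape, phase, dtype=object)
        return PhaseLabels(labels, smoothed, float(values[0]), cutoff, stride)
    thr = _bimodal_threshold(values) if threshold is None else float(threshold)
    labels = np.where(smoothed < thr, "gel", "liquid").astype(object)
    return PhaseLabels(labels, smoothed, thr, cutoff, stride)


def phase_fractions(
    labels: PhaseLabels,
    masses: np.ndarray,
    lipid_types: np.ndarray | None = None,
):
    """Mass-weighted phase bookkeeping.

    Returns a dict with ``gel_percent``/``liquid_percent`` per frame
    (summing to 100 exactly) and, when *lipid_types* is given, the mass
    percentage of each lipid type found in each phase per frame.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    gel = labels.gel_mask()
    total = masses.sum()
    gel_mass = (gel * masses).sum(axis=1)
    out = {
        "gel_percent": 100.0 * gel_mass / total,
        "liquid_percent": 100.0 * (total - gel_mass) / total,
    }
    if lipid_types is not None:
        lipid_types = np.asarray(lipid_types)
        per_type = {}
        for t in np.unique(lipid_types):
            sel = lipid_types == t
            t_mass = masses[sel].sum()
            t_gel = (gel[:, sel] * masses[sel]).sum(axis=1)
            per_type[str(t)] = {
                "gel_percent": 100.0 * t_gel / t_mass,
                "liquid_percent": 100.0 * (t_mass - t_gel) / t_mass,
            }
        out["per_type"] = per_type
    return out
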