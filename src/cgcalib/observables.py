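"""Top-down bilayer observables: area per lipid, head-to-head thickness,
tail tilt, and percentage deviations from experimental targets.

Conventions: the bilayer normal is the z axis; boxes are orthorhombic.
Averages are taken over the final half of the frames (the analysis
window), treating the first half as equilibration.  D_HH is the
separation of the two phosphate-density peaks along z; the peak of each
leaflet is located as the density-weighted mean of the profile bins
within 75% of that leaflet's maximum, after re-centering the membrane
center of mass to z = 0 every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BilayerObservables",
    "InvalidObservableError",
    "area_per_lipid",
    "dhh_thickness",
    "density_profile",
    "percent_deviation",
    "tilt_angle",
]

DENSITY_BIN_WIDTH = 1.0  # Å
PEAK_THRESHOLD = 0.75    # fraction of leaflet maximum used for the centroid


class InvalidObservableError(ValueError):
    """A structural observable could not be computed (e.g. destroyed bilayer)."""


@dataclass
class BilayerObservables:
    apl: float                      # Å² per lipid
    dhh: float                      # Å
    tilt: float | None = None       # degrees
    apl_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    dhh_series: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.apl <= 0 or self.dhh <= 0:
            raise InvalidObservableError("APL and D_HH must be positive")
        if self.tilt is not None and not (0.0 <= self.tilt <= 90.0):
            raise InvalidObservableError("tilt must lie in [0, 90] degrees")


def _analysis_window(n_frames: int) -> slice:
    return slice(n_frames // 2, n_frames)


def area_per_lipid(box_nm: np.ndarray, n_lipids: int, window: bool = True) -> float:
    """Mean lateral box area per lipid per leaflet, in Å².

    box_nm: (n_frames, 3) orthorhombic box lengths in nm.  The bilayer has
    n_lipids/2 lipids per leaflet.
    """
    if n_lipids % 2 != 0:
        raise ValueError("n_lipids must be even (two leaflets)")
    box_nm = np.atleast_2d(np.asarray(box_nm, dtype=float))
    sel = _analysis_window(box_nm.shape[0]) if window else slice(None)
    area_A2 = box_nm[sel, 0] * box_nm[sel, 1] * 100.0  # nm² -> Å²
    return float(np.mean(area_A2 / (n_lipids / 2)))


def density_profile(z_A: np.ndarray, bin_width: float = DENSITY_BIN_WIDTH):
    """Number-density histogram of z positions (Å), symmetric about 0."""
    z_A = np.asarray(z_A, dtype=float)
    half = max(np.abs(z_A).max() + 2 * bin_width, 5 * bin_width)
    # symmetric integer number of bins either side of z = 0, so that a
    # z-mirrored profile is the exact mirror of the original
    n_half = int(np.ceil(half / bin_width))
    edges = (np.arange(-n_half, n_half + 1) * bin_width)
    counts, edges = np.histogram(z_A, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def _leaflet_peak(centers: np.ndarray, counts: np.ndarray) -> float:
    """Density-weighted mean of the bins within PEAK_THRESHOLD of the max."""
    if counts.sum() == 0:
        raise InvalidObservableError("empty leaflet density profile")
    keep = counts >= PEAK_THRESHOLD * counts.max()
    return float(np.average(centers[keep], weights=counts[keep]))


def dhh_thickness(
    phosphate_z_nm: np.ndarray,
    bin_width: float = DENSITY_BIN_WIDTH,
    window: bool = True,
) -> float:
    """Phosphate-peak-to-peak bilayer thickness along z, in Å.

    phosphate_z_nm: (n_frames, n_phosphates) z coordinates in nm.  Each
    frame is re-centered on the mean phosphate z (membrane center proxy)
    before the profile is accumulated; the two leaflets are split at
    z = 0 and each peak located by the 75%-threshold centroid rule.
    """
    z = np.atleast_2d(np.asarray(phosphate_z_nm, dtype=float))
    sel = _analysis_window(z.shape[0]) if window else slice(None)
    z = z[sel]
    if z.size < 100:
        raise ValueError("need at least 100 phosphate samples for a density profile")
    z_centered_A = (z - z.mean(axis=1, keepdims=True)) * 10.0
    centers, counts = density_profile(z_centered_A.ravel(), bin_width)
    upper = centers > 0
    lower = ~upper
    if counts[upper].sum() == 0 or counts[lower].sum() == 0:
        raise InvalidObservableError("unimodal phosphate profile: bilayer destroyed?")
    peak_up = _leaflet_peak(centers[upper], counts[upper])
    peak_dn = _leaflet_peak(centers[lower], counts[lower])
    # a genuine bilayer has well-separated peaks; overlapping leaflets are
    # flagged rather than reported as a tiny thickness
    if peak_up - peak_dn < 2 * bin_width:
        raise InvalidObservableError("leaflet peaks not separated: bilayer destroyed?")
    return float(peak_up - peak_dn)


def percent_deviation(sim_value: float, exp_value: float) -> float:
    """Signed percentage deviation 100*(sim - exp)/exp."""
    if exp_value <= 0:
        raise ValueError("experimental value must be positive")
    return 100.0 * (sim_value - exp_value) / exp_value


def tilt_angle(tail_vectors: np.ndarray) -> float:
    """Mean angle (degrees) between per-lipid tail vectors and the z axis.

    tail_vectors: (..., 3) array of first-to-last tail bead vectors.  The
    absolute value of the z component makes the result leaflet-sign
    independent, so the angle lies in [0°, 90°].
    """
    v = np.asarray(tail_vectors, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length tail vector")
    cosang = np.abs(v[:, 2]) / norms
    return float(np.mean(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))))
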