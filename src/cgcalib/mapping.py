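"""Projection of all-atom trajectories onto CG beads and geometry extraction.

Bead positions are mass-weighted centers of their mapped atoms, computed
per frame after making each bead whole across periodic boundaries.  Bond
lengths use the minimal-image convention in orthorhombic boxes; angles
are unaffected by the box once the three beads are made whole relative
to the central one.

Histogram grids are fixed module-wide: bonds on 0.05 Å bins over
[0, 15 Å], angles on 2° bins over [0°, 180°] — fine relative to the
0.2 Å / 10° scales on which distribution mismatches are judged, and the
Wasserstein metric used downstream is robust to binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import BuildingBlockLibrary, LipidTopology, canonical_key

__all__ = [
    "BOND_BIN_EDGES",
    "ANGLE_BIN_EDGES",
    "GeomDistribution",
    "MappedTrajectory",
    "MappingError",
    "map_trajectory",
    "load_aa_trajectory",
    "measure_terms",
    "histogram",
]

BOND_BIN_EDGES = np.arange(0.0, 15.0 + 0.05 / 2, 0.05)   # Å
ANGLE_BIN_EDGES = np.arange(0.0, 180.0 + 1.0, 2.0)       # degrees


class MappingError(ValueError):
    pass


@dataclass
class MappedTrajectory:
    """CG bead coordinates per frame.

    coords: (n_frames, n_beads, 3) in nm; box: (n_frames, 3) orthorhombic
    box lengths in nm; bead_map: list of (lipid_instance_index,
    topology_index, bead_index_within_lipid).
    """

    coords: np.ndarray
    box: np.ndarray
    bead_map: list[tuple[int, int, int]]
    topologies: tuple[LipidTopology, ...]
    lipid_of_instance: tuple[int, ...]  # topology index per lipid instance

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise MappingError("need at least one frame of bead coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise MappingError("non-finite bead coordinates")
        if np.any(self.box <= 0):
            raise MappingError("box dimensions must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class GeomDistribution:
    """Normalized histogram of bond lengths (Å) or angle values (degrees)."""

    kind: str
    bin_edges: np.ndarray
    masses: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.size != self.bin_edges.size - 1:
            raise ValueError("masses must have one entry per bin")
        if np.any(self.masses < 0):
            raise ValueError("negative histogram mass")
        total = self.masses.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses must sum to 1, got {total}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def units(self) -> str:
        return "angstrom" if self.kind == "bond" else "degree"

    def mean(self) -> float:
        return float(np.dot(self.bin_centers, self.masses))

    def to_table(self) -> str:
        lines = ["# bin_center\tmass"]
        lines += [f"{c:.6g}\t{m:.10g}" for c, m in zip(self.bin_centers, self.masses)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, kind: str, n_samples: int = 0) -> "GeomDistribution":
        centers, masses = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, m = line.split()
            centers.append(float(c))
            masses.append(float(m))
        edges = BOND_BIN_EDGES if kind == "bond" else ANGLE_BIN_EDGES
        expected = 0.5 * (edges[:-1] + edges[1:])
        if len(centers) != expected.size or not np.allclose(centers, expected):
            raise ValueError("table bin centers do not match the module grid")
        m = np.asarray(masses, dtype=float)
        return cls(kind, edges, m / m.sum(), n_samples)


def _minimal_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def map_trajectory(
    aa_coords: np.ndarray,
    box: np.ndarray,
    masses: np.ndarray,
    topologies,
    lipid_of_instance,
    atom_offsets,
) -> MappedTrajectory:
    """Map AA coordinates to bead centers of mass.

    aa_coords: (n_frames, n_atoms, 3) nm; box: (n_frames, 3) nm;
    masses: (n_atoms,) amu.  ``lipid_of_instance[i]`` gives the topology
    index of lipid instance i and ``atom_offsets[i]`` the index of its
    first atom; each bead's ``mapped_atoms`` are relative to that offset.
    Atoms of a bead are made whole relative to the bead's first atom
    before the mass-weighted average, so beads split across the periodic
    boundary map correctly.
    """
    aa_coords = np.asarray(aa_coords, dtype=float)
    box = np.asarray(box, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if aa_coords.ndim != 3:
        raise MappingError("aa_coords must be (n_frames, n_atoms, 3)")
    n_frames, n_atoms = aa_coords.shape[:2]
    topologies = tuple(topologies)

    bead_map: list[tuple[int, int, int]] = []
    groups: list[np.ndarray] = []
    for inst, ti in enumerate(lipid_of_instance):
        topo = topologies[ti]
        off = atom_offsets[inst]
        for bi, bead in enumerate(topo.beads):
            idx = np.asarray(bead.mapped_atoms, dtype=int) + off
            if idx.min() < 0 or idx.max() >= n_atoms:
                raise MappingError(
                    f"lipid instance {inst} bead {bead.name}: atom index out of range"
                )
            bead_map.append((inst, ti, bi))
            groups.append(idx)

    coords = np.empty((n_frames, len(groups), 3))
    for f in range(n_frames):
        b = box[f]
        frame = aa_coords[f]
        for g, idx in enumerate(groups):
            pts = frame[idx]
            ref = pts[0]
            whole = ref + _minimal_image(pts - ref, b)
            w = masses[idx]
            coords[f, g] = np.average(whole, axis=0, weights=w)
    return MappedTrajectory(coords, box, bead_map, topologies, tuple(lipid_of_instance))


def load_aa_trajectory(
    structure_file: str,
    trajectory_file: str | None,
    topologies,
    lipid_of_instance,
    atom_offsets,
) -> MappedTrajectory:
    """Read a GRO (+ optional XTC/TRR) file pair via MDAnalysis and map it."""
    import MDAnalysis as mda

    u = (
        mda.Universe(structure_file, trajectory_file)
        if trajectory_file
        else mda.Universe(structure_file)
    )
    frames, boxes = [], []
    for _ in u.trajectory:
        frames.append(u.atoms.positions / 10.0)          # Å -> nm
        boxes.append(np.asarray(u.dimensions[:3]) / 10.0)
    try:
        masses = u.atoms.masses.copy()
    except mda.exceptions.NoDataError:
        masses = np.ones(len(u.atoms))
    if not np.any(masses > 0):  # element guessing failed: equal weights
        masses = np.ones(len(u.atoms))
    return map_trajectory(
        np.array(frames), np.array(boxes), masses,
        topologies, lipid_of_instance, atom_offsets,
    )


def measure_terms(
    traj: MappedTrajectory,
    library: BuildingBlockLibrary,
    topologies=None,
) -> dict[tuple[str, tuple[str, ...]], np.ndarray]:
    """Pool per-frame, per-instance bond lengths (Å) and angles (degrees)
    by building block.

    Bond vectors use the minimal image; angle values land in [0°, 180°].
    """
    topologies = traj.topologies if topologies is None else tuple(topologies)
    samples: dict[tuple[str, tuple[str, ...]], list] = {
        (b.kind, b.key): [] for b in library
    }
    # bead index lookup: (instance, bead-within-lipid) -> global bead index
    index = {(inst, bi): g for g, (inst, _ti, bi) in enumerate(traj.bead_map)}
    for inst, ti in enumerate(traj.lipid_of_instance):
        topo = topologies[ti]
        for i, j in topo.bonds:
            key = ("bond", canonical_key(topo.bead_types((i, j))))
            gi, gj = index[(inst, i)], index[(inst, j)]
            d = _minimal_image(
                traj.coords[:, gj] - traj.coords[:, gi], traj.box
            )
            samples[key].append(np.linalg.norm(d, axis=1) * 10.0)  # nm -> Å
        for i, j, k in topo.angles:
            key = ("angle", canonical_key(topo.bead_types((i, j, k))))
            gi, gj, gk = index[(inst, i)], index[(inst, j)], index[(inst, k)]
            v1 = _minimal_image(traj.coords[:, gi] - traj.coords[:, gj], traj.box)
            v2 = _minimal_image(traj.coords[:, gk] - traj.coords[:, gj], traj.box)
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            samples[key].append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return {
        k: (np.concatenate(v) if v else np.empty(0)) for k, v in samples.items()
    }


def histogram(samples, kind: str) -> GeomDistribution:
    """Normalized histogram of bond (Å) or angle (degree) samples on the
    module's fixed grid."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty sample set")
    edges = BOND_BIN_EDGES if kind == "bond" else ANGLE_BIN_EDGES
    if kind == "bond" and samples.max() >= edges[-1]:
        raise ValueError(
            f"bond sample {samples.max():.2f} Å outside the fixed grid"
        )
    counts, _ = np.histogram(np.clip(samples, edges[0], edges[-1] - 1e-12), bins=edges)
    masses = counts / counts.sum()
    return GeomDistribution(kind, edges, masses, int(samples.size))
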