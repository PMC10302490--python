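"""Coarse-grained lipid topologies and shared bonded building blocks.

A CG lipid is an ordered list of beads (Martini-type labels such as
``Q1``, ``SN4a``, ``C1``) with harmonic bonds and angles between them.
Bonded terms are classified into *building blocks* keyed by the tuple of
bead types they involve, so that chemically equivalent terms share one
(equilibrium, force constant) pair across every lipid in a training set.
The free parameters of all blocks are flattened into a single vector for
the optimizer.

Internal units follow GROMACS conventions: bond lengths in nm, angles in
degrees, force constants in kJ mol^-1 nm^-2 (bonds) or kJ mol^-1 rad^-2
(angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeadSpec",
    "LipidTopology",
    "BuildingBlock",
    "BuildingBlockLibrary",
    "ParameterVector",
    "TopologyError",
    "canonical_key",
    "classify_terms",
    "count_free_parameters",
    "encode",
    "decode",
    "write_itp",
    "read_itp",
]

LINEAR_ANGLE_DEG = 180.0

# Default search bounds used when a block does not carry explicit ones.
DEFAULT_BOND_LENGTH_BOUNDS = (0.2, 0.8)        # nm
DEFAULT_BOND_FORCE_BOUNDS = (500.0, 10000.0)   # kJ/mol/nm^2
DEFAULT_ANGLE_DEG_BOUNDS = (60.0, 180.0)       # degrees
DEFAULT_ANGLE_FORCE_BOUNDS = (10.0, 500.0)     # kJ/mol/rad^2


class TopologyError(ValueError):
    """Raised for inconsistent bead/bond/angle definitions."""


class EncodingError(ValueError):
    """Raised when a parameter vector does not match a library layout."""


@dataclass(frozen=True)
class BeadSpec:
    """One CG bead and the all-atom atoms it maps.

    ``size_class`` must agree with the Martini naming convention: types
    starting with ``S`` are small beads, with ``T`` tiny, all others
    regular.
    """

    name: str
    bead_type: str
    mapped_atoms: tuple[int, ...] = ()
    size_class: str = ""

    def __post_init__(self):
        object.__setattr__(self, "mapped_atoms", tuple(self.mapped_atoms))
        inferred = _size_class_of(self.bead_type)
        if not self.size_class:
            object.__setattr__(self, "size_class", inferred)
        elif self.size_class != inferred:
            raise TopologyError(
                f"bead {self.name}: size_class {self.size_class!r} conflicts "
                f"with type {self.bead_type!r} (expected {inferred!r})"
            )
        if self.size_class not in ("regular", "small", "tiny"):
            raise TopologyError(f"bad size_class {self.size_class!r}")


def _size_class_of(bead_type: str) -> str:
    if bead_type.startswith("S"):
        return "small"
    if bead_type.startswith("T"):
        return "tiny"
    return "regular"


@dataclass(frozen=True)
class LipidTopology:
    """Bead-level topology of one lipid species."""

    lipid_name: str
    beads: tuple[BeadSpec, ...]
    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "beads", tuple(self.beads))
        object.__setattr__(self, "bonds", tuple(tuple(b) for b in self.bonds))
        object.__setattr__(self, "angles", tuple(tuple(a) for a in self.angles))
        n = len(self.beads)
        bonded = set()
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"{self.lipid_name}: bad bond ({i},{j})")
            bonded.add(frozenset((i, j)))
        for i, j, k in self.angles:
            if len({i, j, k}) != 3 or not all(0 <= x < n for x in (i, j, k)):
                raise TopologyError(f"{self.lipid_name}: bad angle ({i},{j},{k})")
            if frozenset((i, j)) not in bonded or frozenset((j, k)) not in bonded:
                raise TopologyError(
                    f"{self.lipid_name}: angle ({i},{j},{k}) middle bead "
                    f"not bonded to both flanks"
                )
        if n > 1 and not _connected(n, self.bonds):
            raise TopologyError(f"{self.lipid_name}: bead graph not connected")

    @classmethod
    def from_chain(cls, lipid_name: str, beads, bonds=None) -> "LipidTopology":
        """Build a topology enumerating every connected bead triple as an angle.

        *beads* may be BeadSpec objects or bare bead-type strings.
        """
        beads = tuple(
            b if isinstance(b, BeadSpec) else BeadSpec(f"B{i + 1}", b, (i,))
            for i, b in enumerate(beads)
        )
        n = len(beads)
        if bonds is None:
            bonds = tuple((i, i + 1) for i in range(n - 1))
        bonds = tuple(tuple(b) for b in bonds)
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        angles = []
        for j in range(n):
            nbrs = sorted(adj[j])
            for ai in range(len(nbrs)):
                for bi in range(ai + 1, len(nbrs)):
                    angles.append((nbrs[ai], j, nbrs[bi]))
        return cls(lipid_name, beads, bonds, tuple(angles))

    def bead_types(self, indices) -> tuple[str, ...]:
        return tuple(self.beads[i].bead_type for i in indices)


def _connected(n: int, bonds) -> bool:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def canonical_key(bead_types) -> tuple[str, ...]:
    """Orientation-independent key: the lexicographically smaller of the
    tuple and its reverse. Angles keep the middle bead in place."""
    t = tuple(bead_types)
    return min(t, t[::-1])


@dataclass
class BuildingBlock:
    """One shared bonded term type with its harmonic parameters.

    ``equilibrium`` is in nm (bonds) or degrees (angles).  A block with
    ``equilibrium_fixed`` keeps its equilibrium out of the optimizer's
    parameter vector; for angles this pins a linear (180 deg) term.
    """

    kind: str  # "bond" | "angle"
    key: tuple[str, ...]
    equilibrium: float
    force_constant: float
    equilibrium_fixed: bool = False
    equilibrium_bounds: tuple[float, float] | None = None
    force_bounds: tuple[float, float] | None = None
    n_instances: int = 0

    def __post_init__(self):
        self.key = canonical_key(self.key)
        if self.kind == "bond" and len(self.key) != 2:
            raise TopologyError(f"bond key must have 2 bead types: {self.key}")
        if self.kind == "angle" and len(self.key) != 3:
            raise TopologyError(f"angle key must have 3 bead types: {self.key}")
        if self.kind not in ("bond", "angle"):
            raise TopologyError(f"bad block kind {self.kind!r}")
        if self.equilibrium_fixed:
            if self.kind != "angle":
                raise TopologyError("equilibrium_fixed applies to angles only")
            self.equilibrium = LINEAR_ANGLE_DEG
        if self.equilibrium_bounds is None:
            self.equilibrium_bounds = (
                DEFAULT_BOND_LENGTH_BOUNDS if self.kind == "bond"
                else DEFAULT_ANGLE_DEG_BOUNDS
            )
        if self.force_bounds is None:
            self.force_bounds = (
                DEFAULT_BOND_FORCE_BOUNDS if self.kind == "bond"
                else DEFAULT_ANGLE_FORCE_BOUNDS
            )
        for lo, hi in (self.equilibrium_bounds, self.force_bounds):
            if not lo < hi:
                raise TopologyError(f"bounds must satisfy lo < hi, got ({lo},{hi})")

    @property
    def free_roles(self) -> tuple[str, ...]:
        if self.equilibrium_fixed:
            return ("force_constant",)
        return ("equilibrium", "force_constant")


@dataclass
class BuildingBlockLibrary:
    """All building blocks of a representation, keyed by (kind, key)."""

    blocks: dict[tuple[str, tuple[str, ...]], BuildingBlock] = field(default_factory=dict)

    def add(self, block: BuildingBlock) -> None:
        k = (block.kind, block.key)
        if k in self.blocks:
            raise TopologyError(f"duplicate block {k}")
        self.blocks[k] = block

    def get(self, kind: str, bead_types) -> BuildingBlock:
        k = (kind, canonical_key(bead_types))
        try:
            return self.blocks[k]
        except KeyError:
            raise TopologyError(f"no building block for {k}") from None

    def bonds(self) -> list[BuildingBlock]:
        return [b for b in self.blocks.values() if b.kind == "bond"]

    def angles(self) -> list[BuildingBlock]:
        return [b for b in self.blocks.values() if b.kind == "angle"]

    def copy(self) -> "BuildingBlockLibrary":
        return BuildingBlockLibrary(
            {k: replace(b) for k, b in self.blocks.items()}
        )

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks.values())


@dataclass(frozen=True)
class ParameterVector:
    """Flat encoding of all free block parameters, with a stable layout.

    ``layout[i]`` is ``(kind, key, role)`` with role in
    {"equilibrium", "force_constant"}.
    """

    values: np.ndarray
    layout: tuple[tuple[str, tuple[str, ...], str], ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.layout):
            raise EncodingError(
                f"vector length {v.size} != layout length {len(self.layout)}"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.layout)


# ---------------------------------------------------------------------------
# operations


def classify_terms(
    topologies,
    fixed_angle_keys=(),
    default_bond: tuple[float, float] = (0.4, 3000.0),
    default_angle: tuple[float, float] = (120.0, 50.0),
) -> BuildingBlockLibrary:
    """Classify every bond/angle instance across *topologies* into shared
    building blocks keyed by the canonical bead-type tuple.

    ``fixed_angle_keys`` lists angle keys (any orientation) whose
    equilibrium is pinned to 180 degrees.  Parameters are initialized to
    the supplied defaults; instance counts over all lipids are recorded
    on each block.
    """
    fixed = {canonical_key(k) for k in fixed_angle_keys}
    lib = BuildingBlockLibrary()
    counts: dict[tuple[str, tuple[str, ...]], int] = {}
    for topo in topologies:
        for i, j in topo.bonds:
            key = canonical_key(topo.bead_types((i, j)))
            k = ("bond", key)
            if k not in lib.blocks:
                lib.add(BuildingBlock("bond", key, *default_bond))
            counts[k] = counts.get(k, 0) + 1
        for i, j, kk in topo.angles:
            key = canonical_key(topo.bead_types((i, j, kk)))
            k = ("angle", key)
            if k not in lib.blocks:
                lib.add(
                    BuildingBlock(
                        "angle", key, default_angle[0], default_angle[1],
                        equilibrium_fixed=key in fixed,
                    )
                )
            counts[k] = counts.get(k, 0) + 1
    unknown_fixed = fixed - {b.key for b in lib.angles()}
    if unknown_fixed:
        raise TopologyError(f"fixed angle keys not present in any topology: {unknown_fixed}")
    for k, c in counts.items():
        lib.blocks[k].n_instances = c
    return lib


def count_free_parameters(library: BuildingBlockLibrary) -> int:
    """2 per block, minus 1 for each block with a fixed equilibrium."""
    return sum(len(b.free_roles) for b in library)


def _sorted_blocks(library: BuildingBlockLibrary) -> list[BuildingBlock]:
    # bonds before angles, then lexicographic on key: stable across runs
    return sorted(library, key=lambda b: (b.kind != "bond", b.key))


def encode(library: BuildingBlockLibrary) -> ParameterVector:
    """Flatten all free parameters into a vector with a deterministic layout."""
    values, layout = [], []
    for b in _sorted_blocks(library):
        for role in b.free_roles:
            layout.append((b.kind, b.key, role))
            values.append(getattr(b, role))
    return ParameterVector(np.array(values, dtype=float), tuple(layout))


def decode(vector: ParameterVector, library: BuildingBlockLibrary) -> BuildingBlockLibrary:
    """Return a copy of *library* with free parameters set from *vector*.

    Fixed equilibria are untouched.  The vector layout must match the
    library's own encoding layout exactly.
    """
    expected = encode(library)
    if vector.layout != expected.layout:
        raise EncodingError("vector layout does not match library layout")
    out = library.copy()
    for (kind, key, role), v in zip(vector.layout, vector.values):
        setattr(out.blocks[(kind, key)], role, float(v))
    return out


def parameter_bounds(library: BuildingBlockLibrary) -> np.ndarray:
    """(n_free, 2) array of search bounds in layout order."""
    rows = []
    for b in _sorted_blocks(library):
        for role in b.free_roles:
            rows.append(
                b.equilibrium_bounds if role == "equilibrium" else b.force_bounds
            )
    return np.array(rows, dtype=float)


# ---------------------------------------------------------------------------
# GROMACS ITP interchange

_DEG2RAD = np.pi / 180.0


def write_itp(
    library: BuildingBlockLibrary,
    topology: LipidTopology,
    angle_func: int = 2,
) -> str:
    """Emit a GROMACS .itp for one lipid with harmonic bonded terms.

    Bonds use function 1 (b0 in nm, k in kJ/mol/nm^2); angles use
    function 2 (G96 form) or 1 (harmonic), theta0 in degrees, k in
    kJ/mol/rad^2.  Fixed-equilibrium angles are written with theta0=180.
    """
    lines = [
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{topology.lipid_name}  1",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge",
    ]
    for idx, bead in enumerate(topology.beads, start=1):
        lines.append(
            f"{idx:5d}  {bead.bead_type:<6s} 1  {topology.lipid_name:<6s} "
            f"{bead.name:<5s} {idx:4d}  0.0"
        )
    lines += ["", "[ bonds ]", ";  i   j  func  b0(nm)  k"]
    for i, j in topology.bonds:
        blk = library.get("bond", topology.bead_types((i, j)))
        lines.append(
            f"{i + 1:4d} {j + 1:4d}  1  {blk.equilibrium:.6g}  {blk.force_constant:.6g}"
        )
    if topology.angles:
        lines += ["", "[ angles ]", ";  i   j   k  func  theta0(deg)  k"]
        for i, j, k in topology.angles:
            blk = library.get("angle", topology.bead_types((i, j, k)))
            lines.append(
                f"{i + 1:4d} {j + 1:4d} {k + 1:4d}  {angle_func}  "
                f"{blk.equilibrium:.6g}  {blk.force_constant:.6g}"
            )
    return "\n".join(lines) + "\n"


def read_itp(text: str) -> tuple[BuildingBlockLibrary, LipidTopology]:
    """Parse an .itp produced by :func:`write_itp` back into a library
    fragment and topology. Round-trips numerically to 6 significant figures."""
    section = None
    name = "UNK"
    beads: list[BeadSpec] = []
    bonds: list[tuple[int, int]] = []
    angles: list[tuple[int, int, int]] = []
    bond_params: dict[tuple[int, int], tuple[float, float]] = {}
    angle_params: dict[tuple[int, int, int], tuple[float, float]] = {}
    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        parts = line.split()
        if section == "moleculetype":
            name = parts[0]
        elif section == "atoms":
            beads.append(BeadSpec(name=parts[4], bead_type=parts[1], mapped_atoms=(0,)))
        elif section == "bonds":
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            bonds.append((i, j))
            bond_params[(i, j)] = (float(parts[3]), float(parts[4]))
        elif section == "angles":
            i, j, k = (int(p) - 1 for p in parts[:3])
            angles.append((i, j, k))
            angle_params[(i, j, k)] = (float(parts[4]), float(parts[5]))
    topo = LipidTopology(name, tuple(beads), tuple(bonds), tuple(angles))
    lib = BuildingBlockLibrary()
    for (i, j), (b0, k) in bond_params.items():
        key = canonical_key(topo.bead_types((i, j)))
        if ("bond", key) not in lib.blocks:
            lib.add(BuildingBlock("bond", key, b0, k))
    for (i, j, kk), (t0, k) in angle_params.items():
        key = canonical_key(topo.bead_types((i, j, kk)))
        if ("angle", key) not in lib.blocks:
            lib.add(
                BuildingBlock(
                    "angle", key, t0, k,
                    equilibrium_fixed=(t0 == LINEAR_ANGLE_DEG),
                )
            )
    return lib, topo
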