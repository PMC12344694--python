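"""Reference-trajectory handling.

Reads and writes extended-XYZ trajectory files (the de-facto interchange
format for atomistic MD: a per-frame comment line carrying ``Lattice``,
``Properties``, ``energy`` and ``pbc``, followed by per-atom columns),
builds radius-graph neighbor lists under periodic boundary conditions with
the minimum-image convention, and slices trajectories into the subsequence
samples that rollout training consumes: initial positions/velocities plus
the reference forces and *frozen reference edge sets* of the following
``S_max`` frames.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConsistencyError, FormatError, GeometryError, SizeError
from .masses import resolve_masses

__all__ = [
    "Frame",
    "Trajectory",
    "EdgeList",
    "SubsequenceSample",
    "read_trajectory",
    "write_trajectory",
    "radius_neighbors",
    "build_subsequence_dataset",
    "save_samples",
    "load_samples",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One MD snapshot: species, positions (Å), velocities (Å/fs),
    forces (eV/Å), potential energy (eV), cell (3x3 Å) and pbc flags."""

    species: list[str]
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    energy: float
    cell: np.ndarray
    pbc: tuple[bool, bool, bool]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        self.cell = np.asarray(self.cell, dtype=float)
        n = len(self.species)
        if n == 0:
            raise ConsistencyError("frame must contain at least one atom")
        for name, arr in (("positions", self.positions), ("velocities", self.velocities),
                          ("forces", self.forces)):
            if arr.shape != (n, 3):
                raise ConsistencyError(f"{name} has shape {arr.shape}, expected ({n}, 3)")
        if self.cell.shape != (3, 3):
            raise ConsistencyError("cell must be a 3x3 matrix")
        if any(self.pbc) and abs(np.linalg.det(self.cell)) < 1e-12:
            raise GeometryError("cell rows must be linearly independent under pbc")

    @property
    def n_atoms(self) -> int:
        return len(self.species)


@dataclass
class Trajectory:
    """Ordered frames sharing one species list, plus the integration step dt (fs)."""

    frames: list[Frame]
    dt: float

    def __post_init__(self):
        if not self.frames:
            raise ConsistencyError("trajectory must contain at least one frame")
        if self.dt <= 0:
            raise ConsistencyError("dt must be positive")
        ref = self.frames[0].species
        for k, fr in enumerate(self.frames):
            if fr.species != ref:
                raise ConsistencyError(
                    f"frame {k} species/order differ from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def species(self) -> list[str]:
        return self.frames[0].species


@dataclass
class EdgeList:
    """Directed radius-graph edges (i, j) with minimum-image shift triples."""

    src: np.ndarray  # i
    dst: np.ndarray  # j
    shifts: np.ndarray  # integer (E, 3)

    def __post_init__(self):
        self.src = np.asarray(self.src, dtype=np.intp)
        self.dst = np.asarray(self.dst, dtype=np.intp)
        self.shifts = np.asarray(self.shifts, dtype=np.intp)
        if np.any(self.src == self.dst) and np.any(
            (self.src == self.dst) & (self.shifts == 0).all(axis=1)
        ):
            raise GeometryError("self-edges without an image shift are not allowed")

    def __len__(self) -> int:
        return len(self.src)

    def as_set(self) -> set[tuple[int, int]]:
        return set(zip(self.src.tolist(), self.dst.tolist()))


@dataclass
class SubsequenceSample:
    """One training/validation point: the initial state of a subsequence plus
    the reference forces and frozen reference edge sets for S_max steps."""

    species: list[str]
    masses: np.ndarray
    initial_positions: np.ndarray
    initial_velocities: np.ndarray
    dt: float
    reference_forces: np.ndarray  # (S_max, N, 3)
    reference_energy_0: float
    reference_edge_sets: list[EdgeList]
    cell: np.ndarray
    pbc: tuple[bool, bool, bool]
    source: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.reference_forces = np.asarray(self.reference_forces, dtype=float)
        if len(self.reference_edge_sets) != self.s_max:
            raise ConsistencyError("one edge set per reference force frame required")

    @property
    def s_max(self) -> int:
        return self.reference_forces.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.species)


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')

_REQUIRED_COLUMNS = ("species", "pos", "vel", "forces")


def _format_floats(row) -> str:
    return " ".join(f"{v:.17g}" for v in row)


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory as extended-XYZ (full float64 round-trip precision)."""
    lines: list[str] = []
    for fr in traj.frames:
        lines.append(str(fr.n_atoms))
        lattice = " ".join(f"{v:.17g}" for v in fr.cell.reshape(-1))
        pbc = " ".join("T" if p else "F" for p in fr.pbc)
        lines.append(
            f'Lattice="{lattice}" '
            "Properties=species:S:1:pos:R:3:vel:R:3:forces:R:3 "
            f"energy={fr.energy:.17g} dt={traj.dt:.17g} "
            f'pbc="{pbc}"'
        )
        for s, p, v, f in zip(fr.species, fr.positions, fr.velocities, fr.forces):
            lines.append(
                f"{s} {_format_floats(p)} {_format_floats(v)} {_format_floats(f)}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_properties(descriptor: str, frame_idx: int):
    fields = descriptor.split(":")
    if len(fields) % 3 != 0:
        raise FormatError(f"frame {frame_idx}: malformed Properties descriptor {descriptor!r}")
    layout = []  # (name, kind, width, column offset)
    col = 0
    for k in range(0, len(fields), 3):
        name, kind, width = fields[k], fields[k + 1], int(fields[k + 2])
        layout.append((name, kind, width, col))
        col += width
    return layout, col


def read_trajectory(path, dt: float | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory.

    ``dt`` overrides a time step recorded in the file; one of the two must be
    available.  Requires per-atom species, positions, velocities and forces
    and a per-frame energy; a missing column raises :class:`FormatError`
    naming the frame and column.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()

    frames: list[Frame] = []
    file_dt = None
    i = 0
    frame_idx = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n = int(raw[i].strip())
        except ValueError:
            raise FormatError(f"frame {frame_idx}: expected atom count, got {raw[i]!r}")
        if i + 1 + n >= len(raw) + 1 and i + 1 + n > len(raw):
            raise FormatError(f"frame {frame_idx}: truncated frame body")
        comment = raw[i + 1]
        kv = {m.group(1): (m.group(2) if m.group(2) is not None else m.group(3))
              for m in _KV_RE.finditer(comment)}
        if "Properties" not in kv:
            raise FormatError(f"frame {frame_idx}: missing Properties descriptor")
        layout, ncols = _parse_properties(kv["Properties"], frame_idx)
        names = {name for name, *_ in layout}
        for req in _REQUIRED_COLUMNS:
            if req not in names:
                raise FormatError(f"frame {frame_idx}: missing required column {req!r}")
        if "energy" not in kv:
            raise FormatError(f"frame {frame_idx}: missing required column 'energy'")
        if "Lattice" not in kv:
            raise FormatError(f"frame {frame_idx}: missing required column 'Lattice'")
        cell = np.array([float(x) for x in kv["Lattice"].split()], dtype=float)
        if cell.size != 9:
            raise FormatError(f"frame {frame_idx}: Lattice must hold 9 numbers")
        cell = cell.reshape(3, 3)
        pbc_str = kv.get("pbc", "F F F").replace('"', "").split()
        pbc = tuple(tok.upper().startswith("T") for tok in pbc_str)
        if "dt" in kv:
            file_dt = float(kv["dt"])

        body = raw[i + 2 : i + 2 + n]
        if len(body) < n:
            raise FormatError(f"frame {frame_idx}: expected {n} atom lines")
        species: list[str] = []
        arrays = {name: np.empty((n, width)) for name, kind, width, _ in layout if kind == "R"}
        for a, line in enumerate(body):
            toks = line.split()
            if len(toks) < ncols:
                raise FormatError(
                    f"frame {frame_idx}: atom line {a} has {len(toks)} columns, expected {ncols}"
                )
            for name, kind, width, off in layout:
                if kind == "S":
                    species.append(toks[off])
                else:
                    arrays[name][a] = [float(t) for t in toks[off : off + width]]
        frames.append(
            Frame(
                species=species,
                positions=arrays["pos"],
                velocities=arrays["vel"],
                forces=arrays["forces"],
                energy=float(kv["energy"]),
                cell=cell,
                pbc=pbc,
            )
        )
        i += 2 + n
        frame_idx += 1

    effective_dt = dt if dt is not None else file_dt
    if effective_dt is None:
        raise FormatError("no dt recorded in file and none supplied")
    return Trajectory(frames=frames, dt=float(effective_dt))


# ---------------------------------------------------------------------------
# radius graph with minimum-image convention
# ---------------------------------------------------------------------------


def cell_heights(cell: np.ndarray) -> np.ndarray:
    """Perpendicular heights of the cell along each lattice direction."""
    cell = np.asarray(cell, dtype=float)
    volume = abs(np.linalg.det(cell))
    heights = np.empty(3)
    for k in range(3):
        cross = np.cross(cell[(k + 1) % 3], cell[(k + 2) % 3])
        heights[k] = volume / np.linalg.norm(cross)
    return heights


def radius_neighbors(positions, cell=None, pbc=(False, False, False), cutoff: float = 5.0) -> EdgeList:
    """Directed radius graph: edge (i, j) iff the minimum-image distance
    d_ij <= cutoff and i != j.

    Minimum images are searched over the integer shifts {-1, 0, 1} per
    periodic direction, which is exact as long as ``cutoff`` is below half
    the smallest periodic cell height (enforced).
    """
    positions = np.asarray(positions, dtype=float)
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    n = positions.shape[0]
    pbc = tuple(bool(p) for p in pbc)
    if any(pbc):
        if cell is None:
            raise GeometryError("periodic directions require a cell")
        cell = np.asarray(cell, dtype=float)
        heights = cell_heights(cell)
        for k in range(3):
            if pbc[k] and cutoff >= 0.5 * heights[k]:
                raise GeometryError(
                    f"cutoff {cutoff} Å violates the half-cell bound "
                    f"({0.5 * heights[k]:.3f} Å along axis {k})"
                )
        ranges = [(-1, 0, 1) if pbc[k] else (0,) for k in range(3)]
        shifts = np.array(list(itertools.product(*ranges)), dtype=np.intp)
        offsets = shifts @ cell  # (S, 3)
    else:
        shifts = np.zeros((1, 3), dtype=np.intp)
        offsets = np.zeros((1, 3))

    # displacement i -> j under each shift: r_j - r_i + s @ cell
    disp = positions[None, None, :, :] - positions[None, :, None, :] + offsets[:, None, None, :]
    dist = np.linalg.norm(disp, axis=-1)  # (S, N, N)
    best = np.argmin(dist, axis=0)  # (N, N)
    dmin = np.take_along_axis(dist, best[None], axis=0)[0]
    mask = (dmin <= cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)
    return EdgeList(src=src, dst=dst, shifts=shifts[best[src, dst]])


def edge_distances(positions, edges: EdgeList, cell=None) -> np.ndarray:
    """Distances for each directed edge, honoring the stored image shifts."""
    positions = np.asarray(positions, dtype=float)
    rel = positions[edges.dst] - positions[edges.src]
    if cell is not None and len(edges) and edges.shifts.any():
        rel = rel + edges.shifts @ np.asarray(cell, dtype=float)
    return np.linalg.norm(rel, axis=1)


# ---------------------------------------------------------------------------
# subsequence dataset
# ---------------------------------------------------------------------------


def build_subsequence_dataset(
    traj: Trajectory,
    s_max: int,
    cutoff: float,
    masses: dict[str, float] | None = None,
    traj_id: int = 0,
    stride: int = 1,
) -> list[SubsequenceSample]:
    """Slice a trajectory into subsequence samples.

    A sample starting at frame ``i`` stores the positions and velocities of
    frame ``i`` as initial conditions, the reference forces of frames
    ``i .. i+s_max-1``, and the radius-graph edge sets computed from the
    *reference* positions of those frames (the frozen neighborhoods used in
    training-mode rollouts).  With ``stride=1`` a length-L trajectory yields
    L - s_max + 1 samples.
    """
    L = len(traj)
    if s_max < 1:
        raise SizeError("s_max must be >= 1")
    if L < s_max:
        raise SizeError(f"trajectory length {L} < s_max {s_max}")
    mass_arr = resolve_masses(traj.species, masses)
    # one edge set per frame, shared across overlapping samples
    edge_sets = [
        radius_neighbors(fr.positions, fr.cell, fr.pbc, cutoff) for fr in traj.frames
    ]
    forces = np.stack([fr.forces for fr in traj.frames])
    samples = []
    for start in range(0, L - s_max + 1, stride):
        fr0 = traj.frames[start]
        samples.append(
            SubsequenceSample(
                species=traj.species,
                masses=mass_arr,
                initial_positions=fr0.positions.copy(),
                initial_velocities=fr0.velocities.copy(),
                dt=traj.dt,
                reference_forces=forces[start : start + s_max].copy(),
                reference_energy_0=fr0.energy,
                reference_edge_sets=edge_sets[start : start + s_max],
                cell=fr0.cell.copy(),
                pbc=fr0.pbc,
                source=(traj_id, start),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# optional preprocessed-dataset container (HDF5)
# ---------------------------------------------------------------------------

_CONTAINER_VERSION = 1


def save_samples(path, samples: list[SubsequenceSample]) -> None:
    """Store preprocessed samples in a single HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = _CONTAINER_VERSION
        fh.attrs["n_samples"] = len(samples)
        for k, s in enumerate(samples):
            g = fh.create_group(f"sample_{k}")
            g.attrs["species"] = " ".join(s.species)
            g.attrs["dt"] = s.dt
            g.attrs["reference_energy_0"] = s.reference_energy_0
            g.attrs["pbc"] = np.array(s.pbc, dtype=bool)
            g.attrs["source"] = np.array(s.source, dtype=np.int64)
            g["masses"] = s.masses
            g["initial_positions"] = s.initial_positions
            g["initial_velocities"] = s.initial_velocities
            g["reference_forces"] = s.reference_forces
            g["cell"] = s.cell
            for j, e in enumerate(s.reference_edge_sets):
                eg = g.create_group(f"edges_{j}")
                eg["src"] = e.src
                eg["dst"] = e.dst
                eg["shifts"] = e.shifts


def load_samples(path) -> list[SubsequenceSample]:
    import h5py

    samples = []
    with h5py.File(path, "r") as fh:
        if int(fh.attrs["format_version"]) != _CONTAINER_VERSION:
            raise FormatError("unsupported dataset container version")
        for k in range(int(fh.attrs["n_samples"])):
            g = fh[f"sample_{k}"]
            s_max = g["reference_forces"].shape[0]
            edges = [
                EdgeList(
                    src=g[f"edges_{j}"]["src"][...],
                    dst=g[f"edges_{j}"]["dst"][...],
                    shifts=g[f"edges_{j}"]["shifts"][...],
                )
                for j in range(s_max)
            ]
            samples.append(
                SubsequenceSample(
                    species=g.attrs["species"].split(),
                    masses=g["masses"][...],
                    initial_positions=g["initial_positions"][...],
                    initial_velocities=g["initial_velocities"][...],
                    dt=float(g.attrs["dt"]),
                    reference_forces=g["reference_forces"][...],
                    reference_energy_0=float(g.attrs["reference_energy_0"]),
                    reference_edge_sets=edges,
                    cell=g["cell"][...],
                    pbc=tuple(bool(b) for b in g.attrs["pbc"]),
                    source=tuple(int(v) for v in g.attrs["source"]),
                )
            )
    return samples
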