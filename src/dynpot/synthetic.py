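"""Synthetic ground-truth trajectories from an analytic potential.

Emulates the statistical shape of the reference data the trainer is meant
for — microcanonical trajectories of a light diatomic projectile impinging
on a small substrate cluster thermalized at a target temperature, at a
fixed integration time step — while providing *exact* energies and forces
from an analytic potential, so every other module can be tested without
external data.

The default toy system is a 7-atom Lennard-Jones cluster (one heavy
"substrate" species, pentagonal-bipyramid minimum) plus a Morse-bonded
diatomic projectile (light second species) in a vacuum cell.  The two
species have very different force-magnitude distributions, which exercises
the species balancing of the force loss nontrivially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import nve_integrate
from .exceptions import GenerationFault, GeometryError, ParameterError
from .masses import resolve_masses
from .trajectory import Frame, Trajectory
from .units import ACC_CONV, K_B

__all__ = [
    "ToySystem",
    "GeneratorSpec",
    "default_system",
    "analytic_forces",
    "analytic_force_provider",
    "sample_velocities",
    "generate_dataset",
]


@dataclass
class ToySystem:
    """Analytic cluster + projectile system.

    ``lj_table`` maps sorted species pairs to (epsilon [eV], sigma [Å]);
    ``morse`` is (D [eV], a [1/Å], r0 [Å]) for the projectile bond, which
    replaces the pair interaction between the two bonded atoms."""

    species: list[str]
    masses: np.ndarray
    lj_table: dict[tuple[str, str], tuple[float, float]]
    morse: tuple[float, float, float]
    bond: tuple[int, int]
    positions0: np.ndarray
    cell: np.ndarray
    pbc: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions0 = np.asarray(self.positions0, dtype=float)
        self.cell = np.asarray(self.cell, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def projectile_indices(self) -> tuple[int, int]:
        return self.bond

    @property
    def substrate_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_atoms) if i not in self.bond], dtype=np.intp)


@dataclass
class GeneratorSpec:
    """Study conditions of the generated dataset.

    Defaults mirror the reference-data setup the package targets: substrate
    thermalized at 300 K, projectile translational energy 0.125 eV, time
    step 0.5 fs."""

    temperature: float = 300.0  # K
    e_translational: float = 0.125  # eV
    dt: float = 0.5  # fs
    n_steps: int = 300  # frames per trajectory = n_steps + 1
    n_trajectories: int = 20
    seed: int = 0
    equilibration_steps: int = 500
    approach_height: float = 4.5  # Å above the cluster's top atom
    lateral_jitter: float = 0.5  # Å, uniform offset of the aiming point

    def __post_init__(self):
        if self.temperature < 0:
            raise ParameterError("temperature must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")


def _lj7_minimum(r_nn: float) -> np.ndarray:
    """Pentagonal bipyramid (the LJ7 global minimum), nearest-neighbor
    distance r_nn, centered at the origin."""
    ring_r = r_nn / (2.0 * np.sin(np.pi / 5.0))
    angles = 2.0 * np.pi * np.arange(5) / 5.0
    ring = np.stack([ring_r * np.cos(angles), ring_r * np.sin(angles), np.zeros(5)], axis=1)
    apex_h = np.sqrt(max(r_nn**2 - ring_r**2, 1e-12))
    apexes = np.array([[0.0, 0.0, apex_h], [0.0, 0.0, -apex_h]])
    return np.vstack([ring, apexes])


def default_system() -> ToySystem:
    """LJ7 "Pd"-like cluster plus a soft Morse "H2"-like projectile.

    The substrate well depth (0.3 eV) keeps the cluster solid at 300 K
    (k_B T ≈ 0.026 eV); the Morse bond is chosen soft enough that a 0.5 fs
    step resolves the projectile vibration comfortably."""
    sub_sp, proj_sp = "Pd", "H"
    species = [sub_sp] * 7 + [proj_sp] * 2
    masses = resolve_masses(species)
    sigma = 2.55
    positions0 = np.vstack(
        [
            _lj7_minimum(2.0 ** (1.0 / 6.0) * sigma),
            # nominal projectile placement; generate_dataset re-aims it
            np.array([[0.0, 0.0, 8.0], [0.0, 0.0, 8.9]]),
        ]
    )
    return ToySystem(
        species=species,
        masses=masses,
        lj_table={
            (sub_sp, sub_sp): (0.3, sigma),
            tuple(sorted((sub_sp, proj_sp))): (0.05, 2.0),
        },
        morse=(2.5, 1.5, 0.9),
        bond=(7, 8),
        positions0=positions0,
        cell=30.0 * np.eye(3),
        pbc=(False, False, False),
    )


# ---------------------------------------------------------------------------
# analytic potential
# ---------------------------------------------------------------------------


def _pair_terms(system: ToySystem, subset: np.ndarray | None):
    """Pair index arrays (local to ``subset``) and pair parameters."""
    idx = np.arange(system.n_atoms) if subset is None else np.asarray(subset)
    li, lj = np.triu_indices(len(idx), 1)
    gi, gj = idx[li], idx[lj]
    b0, b1 = sorted(system.bond)
    is_bond = (gi == b0) & (gj == b1)
    eps = np.zeros(len(gi))
    sig = np.ones(len(gi))
    for k in range(len(gi)):
        if is_bond[k]:
            continue
        key = tuple(sorted((system.species[gi[k]], system.species[gj[k]])))
        eps[k], sig[k] = system.lj_table.get(key, (0.0, 1.0))
    return li, lj, is_bond, eps, sig


def analytic_forces(system: ToySystem, positions, subset=None):
    """Exact forces (eV/Å) and potential energy (eV) of the analytic PES.

    LJ: 4ε[(σ/r)¹² − (σ/r)⁶]; Morse bond: D[(1 − e^{−a(r−r0)})² − 1]
    (zero at dissociation).  Forces are the exact analytic gradient.
    With ``subset`` given, ``positions`` holds only those atoms and only
    pair terms inside the subset contribute."""
    positions = np.asarray(positions, dtype=float)
    li, lj, is_bond, eps, sig = _pair_terms(system, subset)
    rel = positions[lj] - positions[li]
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-10):
        raise GeometryError("coincident atoms in analytic potential")
    energy = 0.0
    # dV/dr per pair
    dvdr = np.zeros(len(li))
    mask = ~is_bond & (eps > 0)
    if mask.any():
        x6 = (sig[mask] / r[mask]) ** 6
        energy += float(np.sum(4.0 * eps[mask] * (x6**2 - x6)))
        dvdr[mask] = 4.0 * eps[mask] * (-12.0 * x6**2 + 6.0 * x6) / r[mask]
    if is_bond.any():
        d, a, r0 = system.morse
        rb = r[is_bond]
        ex = np.exp(-a * (rb - r0))
        energy += float(np.sum(d * ((1.0 - ex) ** 2 - 1.0)))
        dvdr[is_bond] = 2.0 * d * a * (1.0 - ex) * ex
    # F_i = -dV/dr * dr/dr_i ;  dr/dr_i = -(rel)/r
    fpair = (dvdr / r)[:, None] * rel  # force on atom li from the pair
    forces = np.zeros_like(positions)
    np.add.at(forces, li, fpair)
    np.add.at(forces, lj, -fpair)
    return forces, energy


def analytic_force_provider(system: ToySystem):
    """Force-provider closure with the rollout protocol (edge sets ignored:
    the analytic potential is all-pairs)."""

    def provider(species, positions, cell, pbc, edges):
        from .autodiff import Tensor

        pos = positions.numpy() if isinstance(positions, Tensor) else positions
        return analytic_forces(system, pos)

    return provider


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------


def sample_velocities(masses, temperature: float, seed) -> np.ndarray:
    """Maxwell-Boltzmann velocities (Å/fs) at the given temperature, with
    the center-of-mass drift removed; deterministic per seed."""
    masses = np.asarray(masses, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if temperature == 0:
        return np.zeros((len(masses), 3))
    std = np.sqrt(K_B * temperature * ACC_CONV / masses)
    v = rng.normal(size=(len(masses), 3)) * std[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def _aim_projectile(system: ToySystem, spec: GeneratorSpec, rng: np.random.Generator):
    """Place the bonded diatomic above the cluster with a random bond
    orientation and lateral offset, moving downward with the requested
    translational energy."""
    _, _, r0 = system.morse
    sub = system.substrate_indices
    top_z = system.positions0[sub, 2].max()
    offset = rng.uniform(-spec.lateral_jitter, spec.lateral_jitter, size=2)
    center = np.array([offset[0], offset[1], top_z + spec.approach_height])
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    pos = np.vstack([center - 0.5 * r0 * u, center + 0.5 * r0 * u])
    m_proj = system.masses[list(system.bond)].sum()
    speed = np.sqrt(2.0 * spec.e_translational * ACC_CONV / m_proj)
    vel = np.tile([0.0, 0.0, -speed], (2, 1))
    return pos, vel


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(system: ToySystem, spec: GeneratorSpec) -> list[Trajectory]:
    """Microcanonical reference trajectories with exact analytic forces.

    Per trajectory: the substrate is thermalized (velocity resampling at
    2T — half the kinetic energy flows into potential energy of the cluster
    — followed by a short equilibration run), the projectile is aimed at it,
    and the full system is integrated for ``n_steps`` velocity-Verlet steps,
    giving ``n_steps + 1`` frames carrying exact energies and forces.
    Trajectories differ only through seed-derived initial conditions."""
    trajectories = []
    sub = system.substrate_indices
    proj = list(system.bond)
    for t in range(spec.n_trajectories):
        rng = np.random.default_rng([spec.seed, t])
        # -- substrate thermalization (substrate-only dynamics)
        sub_pos = system.positions0[sub].copy()
        sub_vel = sample_velocities(system.masses[sub], 2.0 * spec.temperature, rng)
        sub_provider = _subsystem_provider(system, sub)
        frames = nve_integrate(
            sub_provider, [system.species[i] for i in sub], sub_pos, sub_vel,
            system.masses[sub], spec.dt, spec.equilibration_steps,
        )
        sub_pos, sub_vel = frames[-1][0], frames[-1][1]
        # re-center the thermalized cluster
        com = (system.masses[sub, None] * sub_pos).sum(axis=0) / system.masses[sub].sum()
        sub_pos = sub_pos - com

        # -- projectile placement and full-system run
        proj_pos, proj_vel = _aim_projectile(system, spec, rng)
        positions = np.zeros((system.n_atoms, 3))
        velocities = np.zeros((system.n_atoms, 3))
        positions[sub], velocities[sub] = sub_pos, sub_vel
        positions[proj], velocities[proj] = proj_pos, proj_vel

        provider = analytic_force_provider(system)
        try:
            raw = nve_integrate(
                provider, system.species, positions, velocities,
                system.masses, spec.dt, spec.n_steps,
            )
        except ParameterError as exc:
            raise GenerationFault(f"trajectory {t}: {exc}") from exc
        for k, (r, v, f, e) in enumerate(raw):
            if not (np.all(np.isfinite(r)) and np.isfinite(e)):
                raise GenerationFault(f"trajectory {t} step {k}: non-finite state")
        trajectories.append(
            Trajectory(
                frames=[
                    Frame(
                        species=list(system.species),
                        positions=r, velocities=v, forces=f, energy=e,
                        cell=system.cell.copy(), pbc=system.pbc,
                    )
                    for r, v, f, e in raw
                ],
                dt=spec.dt,
            )
        )
    return trajectories


def _subsystem_provider(system: ToySystem, subset: np.ndarray):
    def provider(species, positions, cell, pbc, edges):
        return analytic_forces(system, positions, subset=subset)

    return provider
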