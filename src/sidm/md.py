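"""Coarse-grained bead-spring MD engine for copolymer-stabilized interfaces.

Model: monoatomic Lennard-Jones solvent (W, water-like), an optional
oil-like phase (O), and linear block-copolymers built of hydrophilic (H)
and hydrophobic (T) beads. All beads share size sigma and mass m. Pair
interactions are truncated-and-shifted LJ with per-species-pair cutoffs:
2.5 sigma gives a full attractive branch, 2^(1/6) sigma a purely repulsive
(WCA) interaction. Chains are connected by stiff harmonic bonds or FENE
springs (k = 30 eps/sigma^2, l0 = 1.5 sigma); triblock middle blocks can be
made rigid with harmonic angles and a cosine dihedral.

Everything is in reduced LJ units (eps = sigma = m = k_B = 1); the time
unit is sigma*sqrt(m/eps) and the default integration step is 0.006.

The periodic box may carry an xz tilt, which implements Lees-Edwards
sliding-brick boundaries for shear runs (see the nemd module); minimum
images are taken in fractional coordinates, valid for |tilt| <= Lx/2.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SPECIES", "ForceField", "ParticleSystem", "Topology", "ForcesResult",
    "lj_truncated_shifted", "harmonic_bond", "fene_bond", "harmonic_angle",
    "dihedral", "build_cell_list", "compute_forces", "velocity_verlet_step",
    "thermostat_step", "kinetic_temperature", "maxwell_velocities",
    "pressure_tensor", "surface_tension_kirkwood_buff", "density_profile",
    "create_slab_system", "insert_copolymers_by_identity_swap", "Simulation",
]

SPECIES = ("W", "H", "T", "O")
W, H, T, O = 0, 1, 2, 3
WCA_CUT = 2.0 ** (1.0 / 6.0)
DEFAULT_DT = 0.006

# ---------------------------------------------------------------------------
# force field and system containers
# ---------------------------------------------------------------------------


@dataclass
class ForceField:
    """Interaction parameters over the species set {W, H, T, O}.

    pair_epsilon / pair_rcut are symmetric 4x4 matrices indexed by species.
    Bonded defaults follow common bead-spring practice: a stiff harmonic
    bond (k_b = 1000, l0 = 1), the Kremer-Grest FENE spring (k = 30,
    l0 = 1.5), a straight harmonic angle (theta0 = pi) and a cosine
    dihedral k_d (1 + d cos phi).
    """

    pair_epsilon: np.ndarray
    pair_rcut: np.ndarray
    bond_k: float = 1000.0
    bond_l0: float = 1.0
    fene_k: float = 30.0
    fene_l0: float = 1.5
    angle_k: float = 50.0
    angle_theta0: float = math.pi
    dihedral_k: float = 5.0
    dihedral_d: int = 1

    def __post_init__(self) -> None:
        self.pair_epsilon = np.ascontiguousarray(self.pair_epsilon, dtype=float)
        self.pair_rcut = np.ascontiguousarray(self.pair_rcut, dtype=float)
        for name, m in (("pair_epsilon", self.pair_epsilon),
                        ("pair_rcut", self.pair_rcut)):
            if m.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")

    @property
    def max_cutoff(self) -> float:
        return float(self.pair_rcut.max())

    @property
    def pair_shift(self) -> np.ndarray:
        """Energy shift so that u(r_cut) = 0 exactly, per species pair."""
        with np.errstate(divide="ignore"):
            inv6 = self.pair_rcut ** -6.0
        return 4.0 * self.pair_epsilon * (inv6 * inv6 - inv6)

    @classmethod
    def liquid_vapor(cls) -> "ForceField":
        """Equilibrium liquid-vapor systems (W solvent + H/T copolymers).

        H is solvophilic (attractive to W and itself), T solvophobic
        (repulsive to W and H, attractive to itself so tails aggregate).
        """
        eps = np.ones((4, 4))
        rc = np.full((4, 4), 2.5)
        for i, j in ((W, T), (H, T), (T, O), (W, O), (H, O)):
            rc[i, j] = rc[j, i] = WCA_CUT
        rc[O, O] = 2.5
        return cls(pair_epsilon=eps, pair_rcut=rc)

    @classmethod
    def liquid_liquid(cls) -> "ForceField":
        """Symmetric two-phase (W/O) systems with HnTn copolymers.

        Identical pairs plus H-W and T-O keep the attractive branch
        (r_cut = 2.5 sigma); every other pair is purely repulsive.
        """
        eps = np.ones((4, 4))
        rc = np.full((4, 4), WCA_CUT)
        for i in range(4):
            rc[i, i] = 2.5
        rc[H, W] = rc[W, H] = 2.5
        rc[T, O] = rc[O, T] = 2.5
        return cls(pair_epsilon=eps, pair_rcut=rc)


@dataclass
class ParticleSystem:
    """Configuration of the simulation: positions, velocities, species, box.

    The box is orthorhombic with an optional xz tilt (Lees-Edwards offset);
    positions are kept wrapped inside the periodic cell.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    box: np.ndarray
    tilt_xz: float = 0.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must be (N, 3)")
        if self.species.shape != (n,):
            raise ValueError("species must be (N,)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        self.wrap()

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrap(self) -> None:
        """Wrap positions into the (possibly tilted) periodic cell."""
        lx, ly, lz = self.box
        p = self.positions
        kz = np.floor(p[:, 2] / lz)
        p[:, 2] -= kz * lz
        p[:, 0] -= kz * self.tilt_xz
        p[:, 0] -= np.floor((p[:, 0] - self.tilt_xz * p[:, 2] / lz) / lx) * lx
        p[:, 1] -= np.floor(p[:, 1] / ly) * ly

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(self.positions.copy(), self.velocities.copy(),
                              self.species.copy(), self.box.copy(),
                              self.tilt_xz, self.mass)

    def total_momentum(self) -> np.ndarray:
        return self.mass * self.velocities.sum(axis=0)


@dataclass
class Topology:
    """Bonded interactions: bonds (harmonic=0 / FENE=1), angles, dihedrals."""

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_types: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    mol_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_types = np.ascontiguousarray(self.bond_types, dtype=np.int64)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.dihedrals = np.ascontiguousarray(self.dihedrals, dtype=np.int64).reshape(-1, 4)
        if len(self.bond_types) != len(self.bonds):
            raise ValueError("bond_types must match bonds")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def exclusions_csr(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """CSR neighbor-exclusion lists for the non-bonded loop.

        Directly bonded (1-2) pairs of *harmonic* bonds are excluded; FENE
        bonded pairs keep their non-bonded LJ (the FENE spring has no
        repulsive core of its own, so the pair repulsion must act -- the
        Kremer-Grest convention), and 1-3 / 1-4 pairs are always retained.
        """
        lists: list[list[int]] = [[] for _ in range(n)]
        for (i, j), bt in zip(self.bonds, self.bond_types):
            if bt == 0:
                lists[i].append(j)
                lists[j].append(i)
        start = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            start[i + 1] = start[i] + len(lists[i])
        flat = np.zeros(start[-1], dtype=np.int64)
        for i in range(n):
            flat[start[i]:start[i + 1]] = sorted(lists[i])
        return start, flat


@dataclass
class ForcesResult:
    """Forces with the energy breakdown and the (configurational) virial."""

    forces: np.ndarray
    e_pair: float
    e_bond: float
    e_angle: float
    e_dihedral: float
    virial: np.ndarray  # sum over interactions of r (x) f, 3x3

    @property
    def potential_energy(self) -> float:
        return self.e_pair + self.e_bond + self.e_angle + self.e_dihedral


# ---------------------------------------------------------------------------
# scalar potentials (closed forms; the kernels inline the same expressions)
# ---------------------------------------------------------------------------


def lj_truncated_shifted(r: float, eps: float, rcut: float) -> tuple[float, float]:
    """Truncated-and-shifted LJ energy and radial force magnitude at r.

    u(r) = 4 eps [(1/r)^12 - (1/r)^6] - u_LJ(rcut) for r <= rcut, else 0;
    the force is the negative radial derivative of the unshifted form
    (positive = repulsive). sigma = 1 in reduced units.
    """
    if r <= 0:
        raise ValueError("singular overlap: r must be positive")
    if r > rcut:
        return 0.0, 0.0
    inv6 = r ** -6.0
    inv6c = rcut ** -6.0
    u = 4.0 * eps * (inv6 * inv6 - inv6) - 4.0 * eps * (inv6c * inv6c - inv6c)
    f = 24.0 * eps * (2.0 * inv6 * inv6 - inv6) / r
    return u, f


def harmonic_bond(l: float, k_b: float, l_0: float) -> float:
    """Harmonic bond energy (k_b/2)(l - l0)^2."""
    if l < 0:
        raise ValueError("bond length must be non-negative")
    return 0.5 * k_b * (l - l_0) ** 2


def fene_bond(l: float, k_fene: float = 30.0, l_0: float = 1.5) -> float:
    """FENE spring energy -(k/2) l0^2 ln(1 - (l/l0)^2); diverges at l0."""
    if l < 0:
        raise ValueError("bond length must be non-negative")
    if l >= l_0:
        raise ValueError(f"overstretched FENE bond: l={l} >= l0={l_0}")
    return -0.5 * k_fene * l_0 ** 2 * math.log(1.0 - (l / l_0) ** 2)


def harmonic_angle(theta: float, k_a: float, theta_0: float) -> float:
    """Harmonic angle energy (k_a/2)(theta - theta0)^2, theta in radians."""
    return 0.5 * k_a * (theta - theta_0) ** 2


def dihedral(phi: float, k_d: float, d: int = 1) -> float:
    """Cosine dihedral energy k_d (1 + d cos phi), phi in radians."""
    return k_d * (1.0 + d * math.cos(phi))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _nint(x):
    return math.floor(x + 0.5)


@njit(cache=True, inline="always")
def _mi(dx, dy, dz, lx, ly, lz, tilt):
    """Minimum image of a separation vector in the tilted periodic cell."""
    nz = _nint(dz / lz)
    dz -= nz * lz
    dx -= nz * tilt
    dx -= _nint((dx) / lx) * lx
    dy -= _nint(dy / ly) * ly
    return dx, dy, dz


@njit(cache=True)
def _brute_pairs(pos, lx, ly, lz, tilt, cutoff, excl_start, excl_flat, out):
    n = pos.shape[0]
    c2 = cutoff * cutoff
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            skip = False
            for k in range(excl_start[i], excl_start[i + 1]):
                if excl_flat[k] == j:
                    skip = True
                    break
            if skip:
                continue
            dx, dy, dz = _mi(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                             pos[i, 2] - pos[j, 2], lx, ly, lz, tilt)
            if dx * dx + dy * dy + dz * dz <= c2:
                if m >= out.shape[0]:
                    return -1
                out[m, 0] = i
                out[m, 1] = j
                m += 1
    return m


@njit(cache=True)
def _cell_pairs(pos, lx, ly, lz, tilt, cutoff, excl_start, excl_flat, out):
    """Cell-list half-neighbor pair build; returns -2 if box too small."""
    n = pos.shape[0]
    # perpendicular widths of the tilted cell (b and c unaffected by xz tilt)
    wa = lx * lz / math.sqrt(lz * lz + tilt * tilt)
    ncx = int(wa // cutoff)
    ncy = int(ly // cutoff)
    ncz = int(lz // cutoff)
    if ncx < 3 or ncy < 3 or ncz < 3:
        return -2
    ncell = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        uz = pos[i, 2] / lz
        uz -= math.floor(uz)
        ux = (pos[i, 0] - tilt * (pos[i, 2] / lz)) / lx
        ux -= math.floor(ux)
        uy = pos[i, 1] / ly
        uy -= math.floor(uy)
        cx = min(int(ux * ncx), ncx - 1)
        cy = min(int(uy * ncy), ncy - 1)
        cz = min(int(uz * ncz), ncz - 1)
        c = (cz * ncy + cy) * ncx + cx
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    c2 = cutoff * cutoff
    m = 0
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                # same-cell pairs
                for a in range(counts[c], counts[c + 1]):
                    i = order[a]
                    for b in range(a + 1, counts[c + 1]):
                        j = order[b]
                        dx, dy, dz = _mi(pos[i, 0] - pos[j, 0],
                                         pos[i, 1] - pos[j, 1],
                                         pos[i, 2] - pos[j, 2],
                                         lx, ly, lz, tilt)
                        if dx * dx + dy * dy + dz * dz <= c2:
                            skip = False
                            for k in range(excl_start[i], excl_start[i + 1]):
                                if excl_flat[k] == j:
                                    skip = True
                                    break
                            if skip:
                                continue
                            if m >= out.shape[0]:
                                return -1
                            ii, jj = (i, j) if i < j else (j, i)
                            out[m, 0] = ii
                            out[m, 1] = jj
                            m += 1
                # half stencil of neighbor cells
                for dcz in range(-1, 2):
                    for dcy in range(-1, 2):
                        for dcx in range(-1, 2):
                            if not (dcz > 0 or (dcz == 0 and (dcy > 0 or (dcy == 0 and dcx > 0)))):
                                continue
                            ox = (cx + dcx) % ncx
                            oy = (cy + dcy) % ncy
                            oz = (cz + dcz) % ncz
                            c2idx = (oz * ncy + oy) * ncx + ox
                            for a in range(counts[c], counts[c + 1]):
                                i = order[a]
                                for b in range(counts[c2idx], counts[c2idx + 1]):
                                    j = order[b]
                                    dx, dy, dz = _mi(pos[i, 0] - pos[j, 0],
                                                     pos[i, 1] - pos[j, 1],
                                                     pos[i, 2] - pos[j, 2],
                                                     lx, ly, lz, tilt)
                                    if dx * dx + dy * dy + dz * dz <= c2:
                                        skip = False
                                        for k in range(excl_start[i], excl_start[i + 1]):
                                            if excl_flat[k] == j:
                                                skip = True
                                                break
                                        if skip:
                                            continue
                                        if m >= out.shape[0]:
                                            return -1
                                        ii, jj = (i, j) if i < j else (j, i)
                                        out[m, 0] = ii
                                        out[m, 1] = jj
                                        m += 1
    return m


@njit(cache=True)
def _pair_forces(pos, species, eps_mat, rcut_mat, shift_mat,
                 lx, ly, lz, tilt, pairs, npairs, forces, virial):
    e = 0.0
    for k in range(npairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx, dy, dz = _mi(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                         pos[i, 2] - pos[j, 2], lx, ly, lz, tilt)
        r2 = dx * dx + dy * dy + dz * dz
        si = species[i]
        sj = species[j]
        rc = rcut_mat[si, sj]
        if r2 >= rc * rc:
            continue
        if r2 <= 1e-12:
            return np.nan  # singular overlap
        eps = eps_mat[si, sj]
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        e += 4.0 * eps * (inv6 * inv6 - inv6) - shift_mat[si, sj]
        fpr = 24.0 * eps * (2.0 * inv6 * inv6 - inv6) * inv2  # (f/r)
        fx = fpr * dx
        fy = fpr * dy
        fz = fpr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return e


@njit(cache=True)
def _bond_forces(pos, bonds, bond_types, kb, l0b, kf, l0f,
                 lx, ly, lz, tilt, forces, virial, status):
    e = 0.0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx, dy, dz = _mi(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                         pos[i, 2] - pos[j, 2], lx, ly, lz, tilt)
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        if bond_types[k] == 0:
            e += 0.5 * kb * (r - l0b) ** 2
            fpr = -kb * (r - l0b) / max(r, 1e-12)
        else:
            if r >= l0f:
                status[0] = k + 1
                return e
            x = r2 / (l0f * l0f)
            e += -0.5 * kf * l0f * l0f * math.log(1.0 - x)
            fpr = -kf / (1.0 - x)
        fx = fpr * dx
        fy = fpr * dy
        fz = fpr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return e


@njit(cache=True)
def _angle_forces(pos, angles, ka, theta0, lx, ly, lz, tilt, forces, virial):
    e = 0.0
    for k in range(angles.shape[0]):
        i = angles[k, 0]
        j = angles[k, 1]  # central
        l = angles[k, 2]
        ax, ay, az = _mi(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                         pos[i, 2] - pos[j, 2], lx, ly, lz, tilt)
        bx, by, bz = _mi(pos[l, 0] - pos[j, 0], pos[l, 1] - pos[j, 1],
                         pos[l, 2] - pos[j, 2], lx, ly, lz, tilt)
        ra2 = ax * ax + ay * ay + az * az
        rb2 = bx * bx + by * by + bz * bz
        ra = math.sqrt(ra2)
        rb = math.sqrt(rb2)
        c = (ax * bx + ay * by + az * bz) / (ra * rb)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        theta = math.acos(c)
        dtheta = theta - theta0
        e += 0.5 * ka * dtheta * dtheta
        coef = -ka * dtheta / s  # dU/d(cos theta)... chain rule sign folded in
        # grad_i cos(theta) = (b/(ra rb) - c a / ra^2)
        gia = coef * (bx / (ra * rb) - c * ax / ra2)
        gib = coef * (by / (ra * rb) - c * ay / ra2)
        gic = coef * (bz / (ra * rb) - c * az / ra2)
        gla = coef * (ax / (ra * rb) - c * bx / rb2)
        glb = coef * (ay / (ra * rb) - c * by / rb2)
        glc = coef * (az / (ra * rb) - c * bz / rb2)
        # F_i = -dU/dr_i = +(-ka dtheta) * dtheta/dr_i; dtheta/dcos = -1/s
        fi_x = -gia
        fi_y = -gib
        fi_z = -gic
        fl_x = -gla
        fl_y = -glb
        fl_z = -glc
        fj_x = -(fi_x + fl_x)
        fj_y = -(fi_y + fl_y)
        fj_z = -(fi_z + fl_z)
        forces[i, 0] += fi_x
        forces[i, 1] += fi_y
        forces[i, 2] += fi_z
        forces[j, 0] += fj_x
        forces[j, 1] += fj_y
        forces[j, 2] += fj_z
        forces[l, 0] += fl_x
        forces[l, 1] += fl_y
        forces[l, 2] += fl_z
        # virial with central bead as origin (forces sum to zero)
        virial[0, 0] += ax * fi_x + bx * fl_x
        virial[0, 1] += ax * fi_y + bx * fl_y
        virial[0, 2] += ax * fi_z + bx * fl_z
        virial[1, 0] += ay * fi_x + by * fl_x
        virial[1, 1] += ay * fi_y + by * fl_y
        virial[1, 2] += ay * fi_z + by * fl_z
        virial[2, 0] += az * fi_x + bz * fl_x
        virial[2, 1] += az * fi_y + bz * fl_y
        virial[2, 2] += az * fi_z + bz * fl_z
    return e


@njit(cache=True)
def _dihedral_forces(pos, dihedrals, kd, dsign, lx, ly, lz, tilt, forces, virial):
    e = 0.0
    for k in range(dihedrals.shape[0]):
        i1 = dihedrals[k, 0]
        i2 = dihedrals[k, 1]
        i3 = dihedrals[k, 2]
        i4 = dihedrals[k, 3]
        b1x, b1y, b1z = _mi(pos[i2, 0] - pos[i1, 0], pos[i2, 1] - pos[i1, 1],
                            pos[i2, 2] - pos[i1, 2], lx, ly, lz, tilt)
        b2x, b2y, b2z = _mi(pos[i3, 0] - pos[i2, 0], pos[i3, 1] - pos[i2, 1],
                            pos[i3, 2] - pos[i2, 2], lx, ly, lz, tilt)
        b3x, b3y, b3z = _mi(pos[i4, 0] - pos[i3, 0], pos[i4, 1] - pos[i3, 1],
                            pos[i4, 2] - pos[i3, 2], lx, ly, lz, tilt)
        # m = b1 x b2, n = b2 x b3
        mx = b1y * b2z - b1z * b2y
        my = b1z * b2x - b1x * b2z
        mz = b1x * b2y - b1y * b2x
        nx = b2y * b3z - b2z * b3y
        ny = b2z * b3x - b2x * b3z
        nz = b2x * b3y - b2y * b3x
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        if m2 < 1e-16 or n2 < 1e-16:
            continue  # collinear: dihedral undefined, zero torque
        b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cosphi = (mx * nx + my * ny + mz * nz) / math.sqrt(m2 * n2)
        sinphi = (mx * b3x + my * b3y + mz * b3z) * b2n / math.sqrt(m2 * n2)
        phi = math.atan2(sinphi, cosphi)
        e += kd * (1.0 + dsign * math.cos(phi))
        dudphi = -kd * dsign * math.sin(phi)
        # dphi/dr via standard bond-vector formulas
        g1x = -b2n / m2 * mx
        g1y = -b2n / m2 * my
        g1z = -b2n / m2 * mz
        g4x = b2n / n2 * nx
        g4y = b2n / n2 * ny
        g4z = b2n / n2 * nz
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        g2x = -g1x - s12 * g1x + s32 * g4x
        g2y = -g1y - s12 * g1y + s32 * g4y
        g2z = -g1z - s12 * g1z + s32 * g4z
        g3x = -g4x + s12 * g1x - s32 * g4x
        g3y = -g4y + s12 * g1y - s32 * g4y
        g3z = -g4z + s12 * g1z - s32 * g4z
        f1x = -dudphi * g1x
        f1y = -dudphi * g1y
        f1z = -dudphi * g1z
        f2x = -dudphi * g2x
        f2y = -dudphi * g2y
        f2z = -dudphi * g2z
        f3x = -dudphi * g3x
        f3y = -dudphi * g3y
        f3z = -dudphi * g3z
        f4x = -dudphi * g4x
        f4y = -dudphi * g4y
        f4z = -dudphi * g4z
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i2, 0] += f2x
        forces[i2, 1] += f2y
        forces[i2, 2] += f2z
        forces[i3, 0] += f3x
        forces[i3, 1] += f3y
        forces[i3, 2] += f3z
        forces[i4, 0] += f4x
        forces[i4, 1] += f4y
        forces[i4, 2] += f4z
        # virial: positions relative to atom 2 (forces sum to zero)
        r1x, r1y, r1z = -b1x, -b1y, -b1z
        r3x, r3y, r3z = b2x, b2y, b2z
        r4x, r4y, r4z = b2x + b3x, b2y + b3y, b2z + b3z
        virial[0, 0] += r1x * f1x + r3x * f3x + r4x * f4x
        virial[0, 1] += r1x * f1y + r3x * f3y + r4x * f4y
        virial[0, 2] += r1x * f1z + r3x * f3z + r4x * f4z
        virial[1, 0] += r1y * f1x + r3y * f3x + r4y * f4x
        virial[1, 1] += r1y * f1y + r3y * f3y + r4y * f4y
        virial[1, 2] += r1y * f1z + r3y * f3z + r4y * f4z
        virial[2, 0] += r1z * f1x + r3z * f3x + r4z * f4x
        virial[2, 1] += r1z * f1y + r3z * f3y + r4z * f4y
        virial[2, 2] += r1z * f1z + r3z * f3z + r4z * f4z
    return e


# ---------------------------------------------------------------------------
# neighbor list and force evaluation
# ---------------------------------------------------------------------------

_EMPTY_EXCL = (np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64))


def _excl_for(system: ParticleSystem, topology: Topology | None):
    if topology is None or topology.n_bonds == 0:
        return np.zeros(system.n + 1, dtype=np.int64), np.zeros(0, dtype=np.int64)
    return topology.exclusions_csr(system.n)


def _pairs_within(system: ParticleSystem, cutoff: float,
                  excl_start, excl_flat) -> np.ndarray:
    """All (i<j) pairs within cutoff, via cell list or brute force fallback."""
    n = system.n
    cap = max(64, int(n * 140))
    lx, ly, lz = system.box
    while True:
        out = np.empty((cap, 2), dtype=np.int64)
        m = _cell_pairs(system.positions, lx, ly, lz, system.tilt_xz, cutoff,
                        excl_start, excl_flat, out)
        if m == -2:
            m = _brute_pairs(system.positions, lx, ly, lz, system.tilt_xz,
                             cutoff, excl_start, excl_flat, out)
        if m >= 0:
            return out[:m]
        cap *= 2


def build_cell_list(system: ParticleSystem, cutoff: float,
                    topology: Topology | None = None) -> np.ndarray:
    """Neighbor pairs within ``cutoff`` (every pair exactly once, i < j).

    Uses a linked-cell search with minimum-image distances; raises if the
    box is too small to hold 3 cells per dimension at the chosen cutoff.
    """
    lx, ly, lz = system.box
    wa = lx * lz / math.sqrt(lz * lz + system.tilt_xz ** 2)
    if min(wa, ly, lz) < 3.0 * cutoff:
        raise ValueError(
            f"box {tuple(system.box)} too small for a cell list at cutoff {cutoff}"
            " (need >= 3 cells per dimension)")
    excl_start, excl_flat = _excl_for(system, topology)
    pairs = _pairs_within(system, cutoff, excl_start, excl_flat)
    # deterministic order
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


class NeighborList:
    """Verlet list with a skin; rebuilt when displacements exceed skin/2."""

    def __init__(self, cutoff: float, skin: float = 0.4):
        self.cutoff = cutoff
        self.skin = skin
        self.pairs: np.ndarray | None = None
        self._accum = 0.0

    def update(self, system: ParticleSystem, excl_start, excl_flat,
               force: bool = False) -> np.ndarray:
        if force or self.pairs is None or self._accum > 0.5 * self.skin:
            self.pairs = _pairs_within(system, self.cutoff + self.skin,
                                       excl_start, excl_flat)
            self._accum = 0.0
        return self.pairs

    def advance(self, max_step_disp: float) -> None:
        self._accum += max_step_disp


def compute_forces(system: ParticleSystem, forcefield: ForceField,
                   topology: Topology | None = None,
                   pairs: np.ndarray | None = None) -> ForcesResult:
    """Evaluate all forces, the energy breakdown and the virial tensor.

    ``pairs`` may be a (possibly padded) candidate pair list from a Verlet
    neighbor list; distances are re-checked against the true per-pair
    cutoffs here. If omitted, pairs are built fresh.
    """
    if pairs is None:
        excl_start, excl_flat = _excl_for(system, topology)
        pairs = _pairs_within(system, forcefield.max_cutoff, excl_start, excl_flat)
    lx, ly, lz = system.box
    forces = np.zeros((system.n, 3))
    virial = np.zeros((3, 3))
    e_pair = _pair_forces(system.positions, system.species,
                          forcefield.pair_epsilon, forcefield.pair_rcut,
                          forcefield.pair_shift, lx, ly, lz, system.tilt_xz,
                          pairs, len(pairs), forces, virial)
    if math.isnan(e_pair):
        raise FloatingPointError("singular particle overlap (r ~ 0)")
    e_bond = e_angle = e_dih = 0.0
    if topology is not None:
        if topology.n_bonds:
            status = np.zeros(1, dtype=np.int64)
            e_bond = _bond_forces(system.positions, topology.bonds,
                                  topology.bond_types,
                                  forcefield.bond_k, forcefield.bond_l0,
                                  forcefield.fene_k, forcefield.fene_l0,
                                  lx, ly, lz, system.tilt_xz, forces, virial,
                                  status)
            if status[0] != 0:
                k = int(status[0] - 1)
                raise FloatingPointError(
                    f"overstretched FENE bond {tuple(topology.bonds[k])}")
        if len(topology.angles):
            e_angle = _angle_forces(system.positions, topology.angles,
                                    forcefield.angle_k, forcefield.angle_theta0,
                                    lx, ly, lz, system.tilt_xz, forces, virial)
        if len(topology.dihedrals):
            e_dih = _dihedral_forces(system.positions, topology.dihedrals,
                                     forcefield.dihedral_k,
                                     float(forcefield.dihedral_d),
                                     lx, ly, lz, system.tilt_xz, forces, virial)
    return ForcesResult(forces, e_pair, e_bond, e_angle, e_dih, virial)


# ---------------------------------------------------------------------------
# integration, thermostat, observables
# ---------------------------------------------------------------------------


def maxwell_velocities(n: int, temperature: float, seed: int = 0,
                       mass: float = 1.0) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the center-of-mass motion removed."""
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, math.sqrt(temperature / mass), size=(n, 3))
    v -= v.mean(axis=0)
    return v


def kinetic_temperature(system: ParticleSystem,
                        components: tuple[int, ...] = (0, 1, 2)) -> float:
    """Instantaneous kinetic temperature from the selected components."""
    v = system.velocities[:, list(components)]
    dof = v.size
    return float(system.mass * np.sum(v * v) / dof)


def velocity_verlet_step(system: ParticleSystem, forces: np.ndarray,
                         force_fn, dt: float = DEFAULT_DT) -> np.ndarray:
    """One NVE velocity-Verlet step (in place); returns the new forces.

    ``force_fn(system) -> ForcesResult`` evaluates forces at the updated
    positions. Aborts on non-finite forces.
    """
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite forces entering integration step")
    inv_m = 1.0 / system.mass
    system.velocities += 0.5 * dt * inv_m * forces
    system.positions += dt * system.velocities
    system.wrap()
    res = force_fn(system)
    if not np.all(np.isfinite(res.forces)):
        raise FloatingPointError("non-finite forces after position update")
    system.velocities += 0.5 * dt * inv_m * res.forces
    return res.forces


def thermostat_step(system: ParticleSystem, t_target: float, damping: float,
                    rng: np.random.Generator | int,
                    dt: float = DEFAULT_DT,
                    components: tuple[int, ...] = (0, 1, 2)) -> None:
    """Langevin (Ornstein-Uhlenbeck) velocity update over one step.

    v <- c v + sqrt((1 - c^2) T / m) xi with c = exp(-dt / damping); exact
    for the OU process, so the long-run kinetic temperature equals
    ``t_target``. Only the listed Cartesian components are thermostatted
    (shear runs leave the flow direction x untouched).
    """
    if t_target <= 0:
        raise ValueError("t_target must be positive")
    if damping <= 0:
        raise ValueError("damping must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    c = math.exp(-dt / damping)
    sd = math.sqrt((1.0 - c * c) * t_target / system.mass)
    comps = list(components)
    noise = rng.normal(0.0, sd, size=(system.n, len(comps)))
    system.velocities[:, comps] = c * system.velocities[:, comps] + noise


def pressure_tensor(system: ParticleSystem, virial: np.ndarray) -> np.ndarray:
    """Instantaneous virial pressure tensor P = (sum m v v + W) / V."""
    v = system.velocities
    kin = system.mass * (v.T @ v)
    return (kin + virial) / system.volume


def surface_tension_kirkwood_buff(pressure: np.ndarray, l_z: float,
                                  n_interfaces: int = 2) -> float:
    """Kirkwood-Buff surface tension of a slab with interfaces normal to z.

    gamma = (L_z / n_interfaces) * [P_zz - (P_xx + P_yy)/2], the mechanical
    route: the deficit of tangential versus normal pressure integrated
    across the box, split over the interfaces.
    """
    p = np.asarray(pressure, dtype=float)
    if p.shape != (3, 3):
        raise ValueError("pressure must be a 3x3 tensor")
    if n_interfaces < 1:
        raise ValueError("slab geometry requires at least one interface")
    return float(l_z / n_interfaces * (p[2, 2] - 0.5 * (p[0, 0] + p[1, 1])))


def density_profile(system: ParticleSystem, n_bins: int,
                    species: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Number-density profile along z. Returns (bin centers, density)."""
    lx, ly, lz = system.box
    sel = slice(None) if species is None else (system.species == species)
    z = system.positions[sel, 2] % lz
    counts, edges = np.histogram(z, bins=n_bins, range=(0.0, lz))
    vol = lx * ly * (lz / n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / vol


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class RunLog:
    """Scalar time series sampled during a run."""

    step: list = field(default_factory=list)
    e_pot: list = field(default_factory=list)
    e_kin: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    pressure: list = field(default_factory=list)  # 3x3 per sample
    sigma_xz: list = field(default_factory=list)

    def as_arrays(self) -> dict:
        return {k: np.asarray(getattr(self, k)) for k in
                ("step", "e_pot", "e_kin", "temperature", "sigma_xz")}


class Simulation:
    """Velocity-Verlet / Langevin (BAOAB) driver with optional box shear.

    With ``thermostat_t`` set, integrates the Langevin equation with the
    BAOAB splitting (half-kick, half-drift, OU velocity update, half-drift,
    half-kick); otherwise plain NVE velocity Verlet. A nonzero
    ``shear_rate`` drives Lees-Edwards sliding-brick boundaries: the box
    tilt advances by rate * Lz * dt per step and particles crossing the z
    boundary pick up the conjugate position and velocity shifts. During
    shear the thermostat acts only on the y and z velocity components.
    """

    def __init__(self, system: ParticleSystem, forcefield: ForceField,
                 topology: Topology | None = None, dt: float = DEFAULT_DT,
                 thermostat_t: float | None = None, damping: float = 1.0,
                 shear_rate: float = 0.0, seed: int = 0, skin: float = 0.4):
        self.system = system
        self.forcefield = forcefield
        self.topology = topology
        self.dt = dt
        self.thermostat_t = thermostat_t
        self.damping = damping
        self.shear_rate = shear_rate
        self.rng = np.random.default_rng(seed)
        self._excl = _excl_for(system, topology)
        self.nlist = NeighborList(forcefield.max_cutoff, skin)
        if shear_rate != 0.0:
            vmax_step = abs(shear_rate) * system.box[2] * dt
            if vmax_step > 0.5 * forcefield.max_cutoff:
                raise ValueError(
                    f"shear rate {shear_rate} moves the boundary image by "
                    f"{vmax_step:.3f} sigma per step; reduce rate or dt")
        self.step_count = 0
        self._forces_res = self._evaluate()

    # -- internals -------------------------------------------------------
    def _evaluate(self) -> ForcesResult:
        pairs = self.nlist.update(self.system, *self._excl)
        return compute_forces(self.system, self.forcefield, self.topology,
                              pairs=pairs)

    def _drift(self, h: float) -> None:
        sysm = self.system
        lx, ly, lz = sysm.box
        sysm.positions += h * sysm.velocities
        if self.shear_rate != 0.0:
            sysm.tilt_xz += self.shear_rate * lz * h
            # reduce the tilt into [-Lx/2, Lx/2] (lattice-equivalent cell)
            sysm.tilt_xz -= lx * np.round(sysm.tilt_xz / lx)
            # z-crossings pick up the Lees-Edwards velocity jump
            kz = np.floor(sysm.positions[:, 2] / lz)
            cross = kz != 0
            if np.any(cross):
                sysm.velocities[cross, 0] -= kz[cross] * self.shear_rate * lz
        sysm.wrap()
        vmax = float(np.sqrt((sysm.velocities ** 2).sum(axis=1).max()))
        self.nlist.advance(vmax * h + abs(self.shear_rate) * lz * h)

    def step(self) -> None:
        sysm = self.system
        dt = self.dt
        inv_m = 1.0 / sysm.mass
        f = self._forces_res.forces
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"non-finite forces at step {self.step_count}")
        sysm.velocities += 0.5 * dt * inv_m * f
        if self.thermostat_t is None:
            self._drift(dt)
        else:
            self._drift(0.5 * dt)
            comps = (1, 2) if self.shear_rate != 0.0 else (0, 1, 2)
            thermostat_step(sysm, self.thermostat_t, self.damping, self.rng,
                            dt=dt, components=comps)
            self._drift(0.5 * dt)
        self._forces_res = self._evaluate()
        sysm.velocities += 0.5 * dt * inv_m * self._forces_res.forces
        self.step_count += 1

    # -- public API ------------------------------------------------------
    @property
    def forces(self) -> np.ndarray:
        return self._forces_res.forces

    @property
    def potential_energy(self) -> float:
        return self._forces_res.potential_energy

    @property
    def kinetic_energy(self) -> float:
        v = self.system.velocities
        return 0.5 * self.system.mass * float(np.sum(v * v))

    @property
    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy

    def pressure(self) -> np.ndarray:
        return pressure_tensor(self.system, self._forces_res.virial)

    def run(self, n_steps: int, sample_every: int = 0,
            store_frames_every: int = 0,
            log: RunLog | None = None) -> tuple[RunLog, list]:
        """Advance ``n_steps``; sample scalars / store frames periodically.

        Frames are (positions, velocities) copies taken every
        ``store_frames_every`` steps. Returns (log, frames).
        """
        if log is None:
            log = RunLog()
        frames: list = []
        for _ in range(n_steps):
            self.step()
            s = self.step_count
            if sample_every and s % sample_every == 0:
                p = self.pressure()
                log.step.append(s)
                log.e_pot.append(self.potential_energy)
                log.e_kin.append(self.kinetic_energy)
                log.temperature.append(kinetic_temperature(self.system))
                log.pressure.append(p)
                # mechanical shear stress (positive for a positive velocity
                # gradient): sigma_xz = -P_xz
                log.sigma_xz.append(float(-p[0, 2]))
            if store_frames_every and s % store_frames_every == 0:
                frames.append((self.system.positions.copy(),
                               self.system.velocities.copy()))
        return log, frames


# ---------------------------------------------------------------------------
# system builders
# ---------------------------------------------------------------------------


def _lattice_positions(n: int, box: np.ndarray, rng=None) -> np.ndarray:
    """n sites of a simple-cubic lattice filling the box (melted later)."""
    per = int(math.ceil(n ** (1.0 / 3.0)))
    # scale per-axis so cells are near-cubic for anisotropic boxes
    vol = float(np.prod(box))
    a = (vol / n) ** (1.0 / 3.0)
    counts = [max(1, int(round(box[d] / a))) for d in range(3)]
    while counts[0] * counts[1] * counts[2] < n:
        d = int(np.argmin([counts[i] * a / box[i] for i in range(3)]))
        counts[d] += 1
    grid = np.stack(np.meshgrid(
        *(np.arange(counts[d]) * (box[d] / counts[d]) + 0.5 * box[d] / counts[d]
          for d in range(3)), indexing="ij"), axis=-1).reshape(-1, 3)
    if rng is not None:
        order = rng.permutation(len(grid))
        grid = grid[order]
    return np.ascontiguousarray(grid[:n])


def create_slab_system(density: float = 0.8,
                       box: tuple[float, float, float] = (12.0, 12.0, 12.0),
                       mode: str = "liquid-vapor",
                       temperature: float = 0.723,
                       forcefield: ForceField | None = None,
                       seed: int = 0,
                       equil_steps: int = 3000,
                       post_steps: int = 3000,
                       extend_factor: float = 92.96 / 46.77,
                       damping: float = 1.0,
                       dt: float = DEFAULT_DT) -> ParticleSystem:
    """Build and equilibrate a two-interface slab system.

    liquid-vapor: a bulk W liquid is thermalized in ``box``, then the box
    is extended along z by ``extend_factor`` (the protocol's ~2x), leaving
    a liquid slab mid-box with two liquid-vapor interfaces normal to z,
    and re-equilibrated for ``post_steps``.

    liquid-liquid: the whole box is filled at ``density`` with an O layer
    sandwiched between two W layers of equal total particle count (two
    W-O interfaces through the periodic boundary at the slab edges).
    """
    box = np.asarray(box, dtype=float)
    n = int(round(density * np.prod(box)))
    if mode == "liquid-liquid":
        n -= n % 2  # the two phases must hold equal particle counts
    if n < 2:
        raise ValueError(f"density {density} and box {tuple(box)} give n={n}")
    rng = np.random.default_rng(seed)
    pos = _lattice_positions(n, box)
    vel = maxwell_velocities(n, temperature, seed=seed + 1)
    if mode == "liquid-vapor":
        species = np.zeros(n, dtype=np.int64)
        ff = forcefield or ForceField.liquid_vapor()
    elif mode == "liquid-liquid":
        # O slab in the middle half, W in the outer quarters (equal counts)
        species = np.where(
            (pos[:, 2] >= 0.25 * box[2]) & (pos[:, 2] < 0.75 * box[2]), O, W
        ).astype(np.int64)
        # identity swaps to balance counts exactly
        n_o = int((species == O).sum())
        imbalance = n_o - n // 2
        if imbalance > 0:
            idx = np.flatnonzero(species == O)
            edge = np.argsort(np.abs(pos[idx, 2] - 0.5 * box[2]))[::-1]
            species[idx[edge[:imbalance]]] = W
        elif imbalance < 0:
            idx = np.flatnonzero(species == W)
            edge = np.argsort(np.abs(pos[idx, 2] - 0.5 * box[2]))
            species[idx[edge[:-imbalance]]] = O
        ff = forcefield or ForceField.liquid_liquid()
    else:
        raise ValueError(f"unknown slab mode {mode!r}")

    system = ParticleSystem(pos, vel, species, box)
    sim = Simulation(system, ff, dt=dt, thermostat_t=temperature,
                     damping=damping, seed=seed + 2)
    sim.run(equil_steps)

    if mode == "liquid-vapor":
        lz_new = box[2] * extend_factor
        shift = 0.5 * (lz_new - box[2])
        system.positions[:, 2] += shift
        system.box = np.array([box[0], box[1], lz_new])
        system.wrap()
        sim2 = Simulation(system, ff, dt=dt, thermostat_t=temperature,
                          damping=damping, seed=seed + 3)
        sim2.run(post_steps)
    logger.info("slab system: mode=%s n=%d box=%s T=%.3f", mode, n,
                np.round(system.box, 2).tolist(), temperature)
    return system


_ARCH_RE = re.compile(r"([HT])(\d+)")


def parse_architecture(architecture: str) -> list[tuple[int, int]]:
    """Parse a block string like 'H30T10' or 'T5H10T5' into (species, count)."""
    blocks = _ARCH_RE.findall(architecture)
    if not blocks or "".join(f"{s}{n}" for s, n in blocks) != architecture:
        raise ValueError(f"cannot parse architecture {architecture!r}")
    return [(H if s == "H" else T, int(c)) for s, c in blocks]


def _interface_planes_z(system: ParticleSystem, n_bins: int = 40) -> np.ndarray:
    """Rough z positions of the two solvent interfaces (half-max crossings)."""
    has_o = np.any(system.species == O)
    _, rho_w = density_profile(system, n_bins, species=W)
    if has_o:
        _, rho_o = density_profile(system, n_bins, species=O)
        diff = rho_w - rho_o
    else:
        diff = rho_w - 0.5 * np.percentile(rho_w, 90)
    centers = (np.arange(n_bins) + 0.5) * system.box[2] / n_bins
    sign = np.sign(diff)
    crossings = []
    for i in range(n_bins):
        j = (i + 1) % n_bins
        if sign[i] != sign[j] and sign[i] != 0:
            z0, z1 = centers[i], centers[j] if j else system.box[2] + centers[0]
            f0, f1 = diff[i], diff[j]
            crossings.append(z0 + (z1 - z0) * f0 / (f0 - f1))
    if len(crossings) < 2:
        raise ValueError("no density transition found; not a slab geometry?")
    # keep the two crossings bounding the largest density contrast
    return np.asarray(sorted(crossings)[:2]) if len(crossings) == 2 else \
        np.asarray(sorted(crossings, key=lambda z: -abs(np.interp(z, centers, diff)))[:2])


def insert_copolymers_by_identity_swap(
        system: ParticleSystem, architecture: str, count: int,
        seed: int = 0, bond_type: str = "harmonic",
        interface_width: float = 2.5,
        max_retries: int = 100) -> tuple[ParticleSystem, Topology]:
    """Convert interfacial solvent particles into block-copolymer chains.

    Chains are created by selecting adjacent particles near an interface,
    connecting them and changing their identity to H/T segments, so the
    overall number density is untouched. In liquid-vapor systems all beads
    come from W; in liquid-liquid (W/O) systems beads destined to be H are
    taken from the W side and T beads from the O side. Chains alternate
    between the two interfaces; triblocks get angles and dihedrals on the
    middle block to make it rigid. Placement is a seeded nearest-neighbor
    walk with bounded retries.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    system = system.copy()
    if count == 0:
        return system, Topology(mol_id=np.full(system.n, -1, dtype=np.int64))
    if bond_type not in ("harmonic", "fene"):
        raise ValueError(f"unknown bond_type {bond_type!r}")
    blocks = parse_architecture(architecture)
    beads_per_chain = sum(c for _, c in blocks)
    target_species = np.concatenate([np.full(c, s, dtype=np.int64)
                                     for s, c in blocks])
    has_o = np.any(system.species == O)
    # source species each bead must be carved from
    source = np.where(target_species == H, W, O) if has_o else \
        np.full(beads_per_chain, W, dtype=np.int64)

    rng = np.random.default_rng(seed)
    planes = _interface_planes_z(system)
    lz = float(system.box[2])
    pos_w = system.positions.copy()
    tree = cKDTree(np.mod(pos_w, system.box), boxsize=system.box)
    max_bond = 1.3 if bond_type == "harmonic" else 1.45
    used = np.zeros(system.n, dtype=bool)
    # only solvent can be converted
    convertible = (system.species == W) | (system.species == O)
    used[~convertible] = True

    def near_plane(z, plane):
        dz = np.abs(z - plane)
        return np.minimum(dz, lz - dz) < interface_width

    def _growth_dz(plane: float) -> float:
        """z direction the walk should grow in: from the W side toward the
        other phase (O side, or simply across the plane for single-solvent
        systems), so species switches along the chain land where that
        species actually lives."""
        z = pos_w[:, 2] % lz
        dz = z - plane
        dz -= lz * np.round(dz / lz)
        near = np.abs(dz) < 4.0
        ref = (system.species == O) if has_o else np.ones(system.n, dtype=bool)
        sel = near & ref
        if not np.any(sel):
            return 1.0
        return 1.0 if np.mean(dz[sel]) >= 0 else -1.0

    chains: list[np.ndarray] = []
    for chain_idx in range(count):
        plane = planes[chain_idx % 2]
        side = "bottom" if chain_idx % 2 == 0 else "top"
        grow = np.array([0.0, 0.0, _growth_dz(plane)])
        cand0 = np.flatnonzero((system.species == source[0]) & ~used &
                               near_plane(pos_w[:, 2] % lz, plane))
        built = None
        for _ in range(max_retries):
            if cand0.size == 0:
                break
            start = int(rng.choice(cand0))
            if used[start]:
                continue
            idxs = [start]
            trial_used = {start}
            ok = True
            for b in range(1, beads_per_chain):
                cur = pos_w[idxs[-1]]
                target = cur + grow  # bias the walk along the interface normal
                neigh = tree.query_ball_point(cur % system.box, max_bond)
                scored = []
                for j in neigh:
                    if used[j] or j in trial_used:
                        continue
                    if system.species[j] != source[b]:
                        continue
                    d = np.linalg.norm(_min_image_np(pos_w[j] - cur, system.box))
                    if d <= 1e-9 or d >= max_bond:
                        continue
                    miss = np.linalg.norm(
                        _min_image_np(pos_w[j] - target, system.box))
                    scored.append((miss, j))
                if not scored:
                    ok = False
                    break
                scored.sort()
                # random tie-breaking among the closest few avoids
                # deterministic dead ends on retry
                pick = scored[int(rng.integers(min(2, len(scored))))][1]
                idxs.append(pick)
                trial_used.add(pick)
            if ok:
                built = np.asarray(idxs, dtype=np.int64)
                break
        if built is None:
            raise RuntimeError(
                f"failed to build chain {chain_idx} ({architecture}) at the "
                f"{side} interface after {max_retries} retries")
        used[built] = True
        chains.append(built)

    # apply identity swaps and register topology
    mol_id = np.full(system.n, -1, dtype=np.int64)
    bonds, btypes, angles, dihedrals = [], [], [], []
    bt_code = 0 if bond_type == "harmonic" else 1
    is_triblock = len(blocks) == 3
    if is_triblock:
        m0 = blocks[0][1]
        m1 = m0 + blocks[1][1]
    for mol, idxs in enumerate(chains):
        system.species[idxs] = target_species
        mol_id[idxs] = mol
        for a, b in zip(idxs[:-1], idxs[1:]):
            bonds.append((a, b))
            btypes.append(bt_code)
        if is_triblock:
            mid = idxs[m0:m1]
            for t in range(len(mid) - 2):
                angles.append((mid[t], mid[t + 1], mid[t + 2]))
            for q in range(len(mid) - 3):
                dihedrals.append((mid[q], mid[q + 1], mid[q + 2], mid[q + 3]))
    topo = Topology(
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_types=np.asarray(btypes, dtype=np.int64),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        dihedrals=np.asarray(dihedrals, dtype=np.int64).reshape(-1, 4),
        mol_id=mol_id,
    )
    logger.info("inserted %d x %s (%d beads converted, %s bonds)",
                count, architecture, count * beads_per_chain, bond_type)
    return system, topo


def _min_image_np(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Orthorhombic minimum image (used only on untilted boxes)."""
    return d - box * np.round(d / box)
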