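"""Implicit-solvent end-state energetics.

Binding free energies are estimated with the single-trajectory protocol:
complex, receptor and ligand energies are all evaluated on the complex-phase
snapshots, so internal bonded terms cancel identically in the difference and
only nonbonded gas terms plus solvation survive:

    dG_bind = dE_gas + dG_sol          (entropy term deliberately zero)
    dE_gas  = dE_ele + dE_vdw
    dG_sol  = dG_polar + dG_nonpolar
    dG_ele_total = dE_ele + dG_polar

The polar solvation term comes from either a Still-formula generalized Born
model with HCT pairwise-descreening effective radii (GB flavor) or a
finite-difference linearized Poisson-Boltzmann solve (PB flavor).  The
nonpolar term is gamma * SASA + beta with Shrake-Rupley accessible areas.

Units: kcal/mol, Angstrom, elementary charges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from coopbind.geometry import SeriesSummary
from coopbind.model_io import Ensemble, Frame, Topology

logger = logging.getLogger(__name__)

#: Coulomb constant, kcal*Angstrom/(mol*e^2)
K_E = 332.0637

_OVERLAP_TOL = 1e-6
_MIN_EFFECTIVE_RADIUS = 0.1


class EnergeticsError(ValueError):
    """Raised for invalid energetic inputs."""


class ConvergenceError(RuntimeError):
    """Raised when the PB grid solve fails to converge."""


@dataclass
class SolventParams:
    """Continuum-solvent and surface-term parameters (config-exposed)."""

    interior_dielectric: float = 1.0
    exterior_dielectric: float = 80.0
    probe_radius: float = 1.4
    gamma: float = 0.0072  # kcal/mol/A^2
    beta: float = 0.0  # kcal/mol
    gb_offset: float = 0.09  # A
    hct_scale: float = 0.8
    pb_grid_spacing: float = 0.5  # A
    pb_padding: float = 10.0  # A
    pb_ionic_strength: float = 0.0  # mol/L
    pb_relaxation: float | None = None  # None = grid-optimal SOR factor
    pb_tolerance: float = 1e-6
    pb_max_iter: int = 20000
    sasa_n_points: int = 960

    def __post_init__(self) -> None:
        if self.interior_dielectric < 1 or self.exterior_dielectric < 1:
            raise EnergeticsError("dielectric constants must be >= 1")
        if self.pb_grid_spacing <= 0:
            raise EnergeticsError("pb_grid_spacing must be > 0")


# ---------------------------------------------------------------------------
# gas-phase nonbonded terms
# ---------------------------------------------------------------------------

def _subset_array(subset: Sequence[int] | np.ndarray, n_atoms: int) -> np.ndarray:
    idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if idx.size == 0:
        raise EnergeticsError("empty atom subset")
    if idx[0] < 0 or idx[-1] >= n_atoms:
        raise EnergeticsError("subset index out of range")
    return idx


def _pair_scales(
    topology: Topology, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular scale matrices (electrostatic, vdW) for a subset.

    Excluded 1-2/1-3 pairs scale to 0; 1-4 pairs to the topology's scale
    factors; everything else to 1.  Diagonal and lower triangle are 0.
    """
    m = idx.size
    pos = {int(a): k for k, a in enumerate(idx)}
    s_ee = np.triu(np.ones((m, m)), k=1)
    s_vdw = s_ee.copy()
    for i, j in topology.exclusions_12_13:
        if i in pos and j in pos:
            a, b = sorted((pos[i], pos[j]))
            s_ee[a, b] = 0.0
            s_vdw[a, b] = 0.0
    for i, j in topology.scaled_14:
        if i in pos and j in pos:
            a, b = sorted((pos[i], pos[j]))
            s_ee[a, b] = topology.ee_scale
            s_vdw[a, b] = topology.vdw_scale
    return s_ee, s_vdw


def _pair_distances(coords: np.ndarray, scales: np.ndarray) -> np.ndarray:
    d = cdist(coords, coords)
    bad = (scales > 0) & (d < _OVERLAP_TOL)
    if np.any(bad):
        a, b = np.argwhere(bad)[0]
        raise EnergeticsError(
            f"overlapping atoms in nonbonded pair (subset positions {a},{b}): "
            f"r < {_OVERLAP_TOL} A"
        )
    return d


def coulomb_energy(
    frame: Frame, topology: Topology, subset: Sequence[int]
) -> float:
    """Pairwise Coulomb energy over non-excluded pairs within ``subset``."""
    idx = _subset_array(subset, topology.n_atoms)
    s_ee, _ = _pair_scales(topology, idx)
    coords = frame.coordinates[idx]
    d = _pair_distances(coords, s_ee)
    q = topology.charges()[idx]
    qq = np.outer(q, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s_ee > 0, s_ee * qq / d, 0.0)
    return float(K_E * terms.sum())


def lj_energy(frame: Frame, topology: Topology, subset: Sequence[int]) -> float:
    """12-6 Lennard-Jones energy over non-excluded pairs within ``subset``.

    Combination rules: rmin_ij = rmin_half_i + rmin_half_j,
    eps_ij = sqrt(eps_i * eps_j).  No distance cutoff.
    """
    idx = _subset_array(subset, topology.n_atoms)
    _, s_vdw = _pair_scales(topology, idx)
    coords = frame.coordinates[idx]
    d = _pair_distances(coords, s_vdw)
    rmh, eps = topology.lj_params()
    rmin = np.add.outer(rmh[idx], rmh[idx])
    epsij = np.sqrt(np.outer(eps[idx], eps[idx]))
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = (rmin / d) ** 6
        terms = np.where(s_vdw > 0, s_vdw * epsij * (x6 * x6 - 2.0 * x6), 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def effective_born_radii(
    frame: Frame,
    topology: Topology,
    subset: Sequence[int],
    params: SolventParams | None = None,
) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii for ``subset`` atoms.

    The inverse effective radius is the inverse reduced intrinsic radius
    (rho_i - offset) minus the analytic Coulomb-field integral of every
    neighbor sphere (scaled reduced radius s*rho_j), so an isolated atom
    recovers rho_i - offset exactly.  Non-positive results are clamped to
    0.1 A with a warning.
    """
    params = params or SolventParams()
    idx = _subset_array(subset, topology.n_atoms)
    rho = topology.born_radii()[idx] - params.gb_offset
    if np.any(rho <= 0):
        raise EnergeticsError("intrinsic radius minus offset must be positive")
    coords = frame.coordinates[idx]
    d = cdist(coords, coords)
    s = params.hct_scale * rho  # scaled reduced neighbor radii
    m = idx.size
    inv_r = 1.0 / rho
    for i in range(m):
        integral = 0.0
        for j in range(m):
            if i == j:
                continue
            integral += _hct_integral(d[i, j], rho[i], s[j])
        inv_r[i] -= integral
    radii = np.empty(m)
    for k in range(m):
        if inv_r[k] <= 0:
            logger.warning(
                "non-positive effective Born radius for atom %d; clamped to %.1f A",
                idx[k],
                _MIN_EFFECTIVE_RADIUS,
            )
            radii[k] = _MIN_EFFECTIVE_RADIUS
        else:
            radii[k] = 1.0 / inv_r[k]
    return radii


def _hct_integral(d: float, rho_i: float, s_j: float) -> float:
    """Analytic Coulomb-field integral of a neighbor sphere (HCT descreening).

    Integral of 1/(4*pi*r^4) over the part of the neighbor sphere (radius
    ``s_j`` at distance ``d``) lying outside the self sphere ``rho_i``.
    """
    if d <= 0:
        raise EnergeticsError("coincident atoms in Born radius computation")
    if d + s_j <= rho_i:  # neighbor buried inside self sphere
        return 0.0
    u = d + s_j
    low = max(rho_i, abs(d - s_j))
    term = (
        1.0 / low
        - 1.0 / u
        + 0.25 * (d - s_j * s_j / d) * (1.0 / (u * u) - 1.0 / (low * low))
        + 0.5 * math.log(low / u) / d
    )
    if rho_i < s_j - d:  # self sphere engulfed by the neighbor
        term += 2.0 * (1.0 / rho_i - 1.0 / low)
    return 0.5 * term


def _f_gb(d: np.ndarray, radii: np.ndarray) -> np.ndarray:
    rr = np.outer(radii, radii)
    return np.sqrt(d * d + rr * np.exp(-(d * d) / (4.0 * rr)))


def gb_pair_energies(
    frame: Frame,
    topology: Topology,
    subset: Sequence[int],
    params: SolventParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair GB polar energies (upper triangle + diagonal) for a subset.

    Returns ``(idx, matrix)`` where ``matrix[a, b]`` for a < b is the full
    unordered-pair cross term and ``matrix[a, a]`` the self term; summing the
    upper triangle including the diagonal gives the total GB polar energy.
    All pairs interact (no exclusions), as is standard for the GB sum.
    """
    params = params or SolventParams()
    idx = _subset_array(subset, topology.n_atoms)
    radii = effective_born_radii(frame, topology, idx, params)
    q = topology.charges()[idx]
    coords = frame.coordinates[idx]
    d = cdist(coords, coords)
    tau = 1.0 / params.interior_dielectric - 1.0 / params.exterior_dielectric
    fgb = _f_gb(d, radii)
    full = -K_E * tau * np.outer(q, q) / fgb
    mat = np.triu(full, k=1) + 0.5 * np.diag(np.diag(full))
    return idx, mat


def gb_polar_energy(
    frame: Frame,
    topology: Topology,
    subset: Sequence[int],
    params: SolventParams | None = None,
) -> float:
    """Still-formula GB polar solvation energy (self terms included)."""
    _, mat = gb_pair_energies(frame, topology, subset, params)
    return float(np.triu(mat).sum())


# ---------------------------------------------------------------------------
# finite-difference Poisson-Boltzmann
# ---------------------------------------------------------------------------

def _spread_charges(
    coords: np.ndarray, charges: np.ndarray, origin: np.ndarray, h: float, shape
) -> np.ndarray:
    """Trilinear charge assignment to grid nodes."""
    q_grid = np.zeros(shape)
    rel = (coords - origin) / h
    base = np.floor(rel).astype(int)
    frac = rel - base
    for (i0, j0, k0), (fx, fy, fz), q in zip(base, frac, charges):
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    q_grid[i0 + di, j0 + dj, k0 + dk] += q * wx * wy * wz
    return q_grid


_EDGE_SAMPLES = 9


def _edge_dielectric(
    coords: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    h: float,
    shape: tuple[int, int, int],
    eps_in: float,
    eps_out: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Harmonic-mean edge dielectric from the fraction of each edge inside
    the solute (sampled at evenly spaced points along the edge).

    The harmonic average of eps over the edge path greatly reduces the
    sharp-boundary discretization error of plain midpoint painting.
    """
    axes = [np.arange(n) * h + o for n, o in zip(shape, origin)]

    def paint(axis: int) -> np.ndarray:
        edge_shape = tuple(
            n - 1 if d == axis else n for d, n in enumerate(shape)
        )
        frac = np.zeros(edge_shape)
        ts = (np.arange(_EDGE_SAMPLES) + 0.5) / _EDGE_SAMPLES
        ax = [a.copy() for a in axes]
        ax[axis] = ax[axis][:-1]
        for t in ts:
            pts_axes = list(ax)
            pts_axes[axis] = pts_axes[axis] + t * h
            mesh = np.meshgrid(*pts_axes, indexing="ij")
            inside = np.zeros(edge_shape, dtype=bool)
            for c, r in zip(coords, radii):
                d2 = (
                    (mesh[0] - c[0]) ** 2
                    + (mesh[1] - c[1]) ** 2
                    + (mesh[2] - c[2]) ** 2
                )
                inside |= d2 < r * r
            frac += inside
        frac /= _EDGE_SAMPLES
        return 1.0 / ((1.0 - frac) / eps_out + frac / eps_in)

    return paint(0), paint(1), paint(2)


def _analytic_potential(
    coords: np.ndarray,
    charges: np.ndarray,
    origin: np.ndarray,
    h: float,
    shape: tuple[int, int, int],
    eps: float,
    kappa: float,
) -> np.ndarray:
    """Superposed Debye-Hueckel/Coulomb potential on every grid node.

    Provides both the Dirichlet boundary values and the interior starting
    guess of the relaxation; distances are floored at one grid spacing to
    keep the guess finite at charge sites.
    """
    axes = [np.arange(n) * h + o for n, o in zip(shape, origin)]
    mesh = np.meshgrid(*axes, indexing="ij")
    phi = np.zeros(shape)
    for c, q in zip(coords, charges):
        r = np.sqrt(
            (mesh[0] - c[0]) ** 2 + (mesh[1] - c[1]) ** 2 + (mesh[2] - c[2]) ** 2
        )
        r = np.maximum(r, h)
        screen = np.exp(-kappa * r) if kappa > 0 else 1.0
        phi += K_E * q * screen / (eps * r)
    return phi


def _optimal_omega(shape: tuple[int, int, int]) -> float:
    """Grid-optimal SOR relaxation factor from the Jacobi spectral radius."""
    rho = np.mean([math.cos(math.pi / (n - 1)) for n in shape])
    return 2.0 / (1.0 + math.sqrt(max(1e-12, 1.0 - rho * rho)))


def _sor_blocks(shape: tuple[int, int, int]):
    """Strided slice tuples implementing red-black Gauss-Seidel ordering.

    Interior nodes split into 8 sub-lattices by index parity; the 4 with even
    parity sum form one color.  Returns per-block slices for the node, its 6
    neighbors, and the 6 incident dielectric edges.
    """
    nx, ny, nz = shape
    blocks = []
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                node = (
                    slice(1 + a, nx - 1, 2),
                    slice(1 + b, ny - 1, 2),
                    slice(1 + c, nz - 1, 2),
                )
                blocks.append(
                    {
                        "color": (a + b + c) % 2,
                        "node": node,
                        "xlo": (slice(a, nx - 2, 2),) + node[1:],
                        "xhi": (slice(2 + a, nx, 2),) + node[1:],
                        "ylo": (node[0], slice(b, ny - 2, 2), node[2]),
                        "yhi": (node[0], slice(2 + b, ny, 2), node[2]),
                        "zlo": node[:2] + (slice(c, nz - 2, 2),),
                        "zhi": node[:2] + (slice(2 + c, nz, 2),),
                        # edge k joins nodes k and k+1 along its axis
                        "ex_lo": (slice(a, nx - 2, 2),) + node[1:],
                        "ex_hi": (slice(1 + a, nx - 1, 2),) + node[1:],
                        "ey_lo": (node[0], slice(b, ny - 2, 2), node[2]),
                        "ey_hi": (node[0], slice(1 + b, ny - 1, 2), node[2]),
                        "ez_lo": node[:2] + (slice(c, nz - 2, 2),),
                        "ez_hi": node[:2] + (slice(1 + c, nz - 1, 2),),
                    }
                )
    return blocks


def _sor_solve(
    phi: np.ndarray,
    eps_x: np.ndarray,
    eps_y: np.ndarray,
    eps_z: np.ndarray,
    source: np.ndarray,
    kappa2_grid: np.ndarray,
    omega: float | None,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Red-black successive over-relaxation for div(eps grad phi) = -source.

    Boundary values of ``phi`` are Dirichlet data and never updated.
    Convergence is declared when the largest potential update falls below
    ``tol``.
    """
    if omega is None:
        omega = _optimal_omega(phi.shape)
    blocks = _sor_blocks(phi.shape)
    cached = []
    for blk in blocks:
        den = (
            eps_x[blk["ex_lo"]]
            + eps_x[blk["ex_hi"]]
            + eps_y[blk["ey_lo"]]
            + eps_y[blk["ey_hi"]]
            + eps_z[blk["ez_lo"]]
            + eps_z[blk["ez_hi"]]
            + kappa2_grid[blk["node"]]
        )
        cached.append((blk, den, source[blk["node"]]))
    max_update = math.inf
    for _ in range(max_iter):
        max_update = 0.0
        for color in (0, 1):
            for blk, den, src in cached:
                if blk["color"] != color or den.size == 0:
                    continue
                num = (
                    eps_x[blk["ex_lo"]] * phi[blk["xlo"]]
                    + eps_x[blk["ex_hi"]] * phi[blk["xhi"]]
                    + eps_y[blk["ey_lo"]] * phi[blk["ylo"]]
                    + eps_y[blk["ey_hi"]] * phi[blk["yhi"]]
                    + eps_z[blk["ez_lo"]] * phi[blk["zlo"]]
                    + eps_z[blk["ez_hi"]] * phi[blk["zhi"]]
                )
                old = phi[blk["node"]]
                delta = omega * ((num + src) / den - old)
                phi[blk["node"]] = old + delta
                if delta.size:
                    max_update = max(max_update, float(np.abs(delta).max()))
        if max_update < tol:
            return phi
    raise ConvergenceError(
        f"PB solver did not converge in {max_iter} iterations "
        f"(last max potential update {max_update:.3e})"
    )


def fd_poisson_boltzmann(
    frame: Frame,
    topology: Topology,
    subset: Sequence[int],
    params: SolventParams | None = None,
) -> float:
    """Polar solvation energy from a finite-difference linearized PB solve.

    Reaction-field energy = grid energy with the heterogeneous dielectric
    (eps_in inside atom spheres, eps_out outside) minus the grid energy of a
    uniform eps_in reference solve on the identical grid and charge
    discretization, so grid self-energy cancels.  Dirichlet boundaries come
    from the analytic Debye-Hueckel/Coulomb potential.
    """
    params = params or SolventParams()
    idx = _subset_array(subset, topology.n_atoms)
    coords = frame.coordinates[idx]
    charges = topology.charges()[idx]
    radii = topology.born_radii()[idx]
    if not np.any(charges != 0):
        return 0.0
    h = params.pb_grid_spacing
    lo = coords.min(axis=0) - radii.max() - params.pb_padding
    hi = coords.max(axis=0) + radii.max() + params.pb_padding
    shape = tuple(int(math.ceil((b - a) / h)) + 1 for a, b in zip(lo, hi))
    origin = lo
    q_grid = _spread_charges(coords, charges, origin, h, shape)
    source = 4.0 * math.pi * K_E * q_grid / h

    # Debye screening (approximate aqueous 298 K form); zero by default
    if params.pb_ionic_strength > 0:
        kappa = math.sqrt(params.pb_ionic_strength) / 3.047  # 1/A
    else:
        kappa = 0.0

    eps_x, eps_y, eps_z = _edge_dielectric(
        coords, radii, origin, h, shape,
        params.interior_dielectric, params.exterior_dielectric,
    )
    kappa2 = np.zeros(shape)
    if kappa > 0:
        # screening acts only where the medium is solvent (approximated by
        # node outside all atom spheres via the x-edge paint at the node)
        solvent = np.ones(shape, dtype=bool)
        axes = [np.arange(n) * h + o for n, o in zip(shape, origin)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        flat = mesh.reshape(-1, 3)
        inside = np.zeros(len(flat), dtype=bool)
        for c, r in zip(coords, radii):
            inside |= np.einsum("ij,ij->i", flat - c, flat - c) < r * r
        solvent = ~inside.reshape(shape)
        kappa2 = np.where(
            solvent, params.exterior_dielectric * kappa * kappa * h * h, 0.0
        )

    phi_solv = _analytic_potential(
        coords, charges, origin, h, shape, params.exterior_dielectric, kappa
    )
    phi_solv = _sor_solve(
        phi_solv, eps_x, eps_y, eps_z, source, kappa2,
        params.pb_relaxation, params.pb_tolerance, params.pb_max_iter,
    )

    eps_in = params.interior_dielectric
    uni = (np.full_like(eps_x, eps_in), np.full_like(eps_y, eps_in),
           np.full_like(eps_z, eps_in))
    phi_ref = _analytic_potential(
        coords, charges, origin, h, shape, eps_in, 0.0
    )
    phi_ref = _sor_solve(
        phi_ref, *uni, source, np.zeros(shape),
        params.pb_relaxation, params.pb_tolerance, params.pb_max_iter,
    )
    return float(0.5 * np.sum(q_grid * (phi_solv - phi_ref)))


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def shrake_rupley_sasa(
    frame: Frame,
    topology: Topology,
    subset: Sequence[int],
    params: SolventParams | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Sample points sit on each atom's probe-inflated sphere (intrinsic Born
    radius + probe); a point is buried when it lies inside another atom's
    inflated sphere.  Exact ties (coincident equal spheres) are resolved by
    atom order, so the union area is preserved.  Returns per-atom areas in
    subset order and their total (Angstrom^2).
    """
    params = params or SolventParams()
    idx = _subset_array(subset, topology.n_atoms)
    coords = frame.coordinates[idx]
    radii = topology.born_radii()[idx] + params.probe_radius
    pts = _fibonacci_sphere(params.sasa_n_points)
    m = idx.size
    areas = np.zeros(m)
    tie = 1e-9
    for i in range(m):
        sphere = coords[i] + radii[i] * pts
        accessible = np.ones(len(sphere), dtype=bool)
        for j in range(m):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= radii[i] + radii[j]:
                continue
            d = np.linalg.norm(sphere - coords[j], axis=1)
            buried = d < radii[j] - tie
            if j < i:
                buried |= d < radii[j] + tie
            accessible &= ~buried
        areas[i] = (
            4.0 * math.pi * radii[i] ** 2 * accessible.sum() / len(sphere)
        )
    return areas, float(areas.sum())


def nonpolar_energy(sasa_total: float, params: SolventParams) -> float:
    """Surface-tension nonpolar solvation term gamma * SASA + beta."""
    return params.gamma * sasa_total + params.beta


# ---------------------------------------------------------------------------
# single-trajectory breakdown
# ---------------------------------------------------------------------------

TERMS = (
    "dE_ele",
    "dE_vdw",
    "dE_gas",
    "dG_nonpolar",
    "dG_sol",
    "dG_ele_total",
    "dG_bind",
)


@dataclass
class PerFrameEnergies:
    """Absolute energy terms of one species in one frame."""

    species: str
    E_bond: float
    E_ang: float
    E_tor: float
    E_vdw: float
    E_ele: float
    G_polar_solv: float
    G_nonpolar: float
    sasa_total: float


@dataclass
class EnergyBreakdown:
    """Frame series and summaries of every binding energy difference term."""

    solvent_model: str
    series: dict[str, np.ndarray]
    ligand_partition: str = "ligand1"

    def summary(self, term: str) -> SeriesSummary:
        return SeriesSummary.from_values(self.series[term])

    @property
    def n_frames(self) -> int:
        return len(self.series["dG_bind"])

    def summaries(self) -> dict[str, SeriesSummary]:
        return {t: self.summary(t) for t in TERMS}


@dataclass
class ResidueContribution:
    """One residue's (or the ligand bucket's) binding-energy contribution."""

    residue_id: tuple[str, int, str] | str
    series: np.ndarray
    summary: SeriesSummary


def _species_subsets(
    topology: Topology,
    ligand_partition: str,
    other_ligand_as_receptor: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(complex, receptor-side, ligand) index arrays for the protocol."""
    lig = topology.partition_indices(ligand_partition)
    if lig.size == 0:
        raise EnergeticsError(f"partition {ligand_partition!r} has no atoms")
    receptor_parts = ["receptor", "cofactor"]
    if other_ligand_as_receptor:
        receptor_parts += [
            p for p in ("ligand1", "ligand2") if p != ligand_partition
        ]
    rec = np.concatenate(
        [topology.partition_indices(p) for p in receptor_parts]
    )
    rec = np.sort(rec)
    if rec.size == 0:
        raise EnergeticsError("receptor side has no atoms")
    cpx = np.sort(np.concatenate([rec, lig]))
    return cpx, rec, lig


def _polar_term(
    frame: Frame,
    topology: Topology,
    subset: np.ndarray,
    params: SolventParams,
    solvent_model: str,
) -> float:
    if solvent_model == "GB":
        return gb_polar_energy(frame, topology, subset, params)
    if solvent_model == "PB":
        return fd_poisson_boltzmann(frame, topology, subset, params)
    raise EnergeticsError(f"unknown solvent model {solvent_model!r}")


def single_trajectory_mmgbsa(
    ensemble: Ensemble,
    params: SolventParams | None = None,
    solvent_model: str = "GB",
    ligand_partition: str = "ligand1",
    other_ligand_as_receptor: bool = True,
) -> EnergyBreakdown:
    """Frame-averaged binding free energy differences (single-trajectory).

    Each term is X_complex - X_receptor - X_ligand evaluated on the same
    complex-phase coordinates; bonded terms cancel identically and are not
    evaluated.  ``other_ligand_as_receptor`` keeps any second ligand on the
    receptor side of the difference (set False to drop it entirely).
    """
    params = params or SolventParams()
    top = ensemble.topology
    cpx, rec, lig = _species_subsets(
        top, ligand_partition, other_ligand_as_receptor
    )
    series = {t: np.zeros(ensemble.n_frames) for t in TERMS}
    for k, frame in enumerate(ensemble.frames):
        d_ele = (
            coulomb_energy(frame, top, cpx)
            - coulomb_energy(frame, top, rec)
            - coulomb_energy(frame, top, lig)
        )
        d_vdw = (
            lj_energy(frame, top, cpx)
            - lj_energy(frame, top, rec)
            - lj_energy(frame, top, lig)
        )
        d_polar = (
            _polar_term(frame, top, cpx, params, solvent_model)
            - _polar_term(frame, top, rec, params, solvent_model)
            - _polar_term(frame, top, lig, params, solvent_model)
        )
        d_np = (
            nonpolar_energy(shrake_rupley_sasa(frame, top, cpx, params)[1], params)
            - nonpolar_energy(shrake_rupley_sasa(frame, top, rec, params)[1], params)
            - nonpolar_energy(shrake_rupley_sasa(frame, top, lig, params)[1], params)
        )
        series["dE_ele"][k] = d_ele
        series["dE_vdw"][k] = d_vdw
        series["dE_gas"][k] = d_ele + d_vdw
        series["dG_nonpolar"][k] = d_np
        series["dG_sol"][k] = d_polar + d_np
        series["dG_ele_total"][k] = d_ele + d_polar
        series["dG_bind"][k] = d_ele + d_vdw + d_polar + d_np
    return EnergyBreakdown(
        solvent_model=solvent_model,
        series=series,
        ligand_partition=ligand_partition,
    )


# ---------------------------------------------------------------------------
# per-residue decomposition (GB path)
# ---------------------------------------------------------------------------

LIGAND_BUCKET = "ligand"


def _pair_energy_matrix(
    frame: Frame, topology: Topology, idx: np.ndarray, kind: str
) -> np.ndarray:
    """Upper-triangular per-pair gas-phase energies for a subset."""
    s_ee, s_vdw = _pair_scales(topology, idx)
    coords = frame.coordinates[idx]
    if kind == "ele":
        d = _pair_distances(coords, s_ee)
        q = topology.charges()[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s_ee > 0, K_E * s_ee * np.outer(q, q) / d, 0.0)
    d = _pair_distances(coords, s_vdw)
    rmh, eps = topology.lj_params()
    rmin = np.add.outer(rmh[idx], rmh[idx])
    epsij = np.sqrt(np.outer(eps[idx], eps[idx]))
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = (rmin / d) ** 6
        return np.where(s_vdw > 0, s_vdw * epsij * (x6 * x6 - 2.0 * x6), 0.0)


def per_residue_decomposition(
    ensemble: Ensemble,
    params: SolventParams | None = None,
    solvent_model: str = "GB",
    ligand_partition: str = "ligand1",
    other_ligand_as_receptor: bool = True,
) -> list[ResidueContribution]:
    """Pairwise split of the GB-path binding free energy per receptor residue.

    Every pairwise term (Coulomb, LJ, GB including self terms, and the
    per-atom SASA nonpolar differences) is assigned half-and-half to the
    residue buckets of its two atoms; ligand atoms accumulate into one
    ``ligand`` bucket.  Bucket sums reproduce the per-frame total binding
    energy to machine precision.  PB is not pairwise-decomposable here.
    """
    if solvent_model != "GB":
        raise EnergeticsError(
            "per-residue decomposition requires the GB path "
            "(PB polar energy is not pairwise-decomposable)"
        )
    params = params or SolventParams()
    top = ensemble.topology
    cpx, rec, lig = _species_subsets(
        top, ligand_partition, other_ligand_as_receptor
    )
    lig_set = set(int(i) for i in lig)

    def bucket_of(atom_index: int):
        if atom_index in lig_set:
            return LIGAND_BUCKET
        return top.residue_of(atom_index)

    bucket_keys: list = []
    for i in cpx:
        b = bucket_of(int(i))
        if b not in bucket_keys:
            bucket_keys.append(b)
    pos_in = {key: k for k, key in enumerate(bucket_keys)}
    acc = np.zeros((len(bucket_keys), ensemble.n_frames))

    for fk, frame in enumerate(ensemble.frames):
        def deposit(idx: np.ndarray, mat: np.ndarray, sign: float) -> None:
            # split each upper-triangle pair term half/half; the diagonal
            # (self terms) lands whole on its atom via row+column symmetry
            per_atom = 0.5 * (mat.sum(axis=0) + mat.sum(axis=1))
            for local, atom in enumerate(idx):
                acc[pos_in[bucket_of(int(atom))], fk] += sign * per_atom[local]

        for kind in ("ele", "vdw"):
            deposit(cpx, np.triu(_pair_energy_matrix(frame, top, cpx, kind), 1), 1.0)
            deposit(rec, np.triu(_pair_energy_matrix(frame, top, rec, kind), 1), -1.0)
            deposit(lig, np.triu(_pair_energy_matrix(frame, top, lig, kind), 1), -1.0)

        for subset, sign in ((cpx, 1.0), (rec, -1.0), (lig, -1.0)):
            sidx, gmat = gb_pair_energies(frame, top, subset, params)
            deposit(sidx, gmat, sign)

        sasa_by_atom = np.zeros(top.n_atoms)
        areas_cpx, _ = shrake_rupley_sasa(frame, top, cpx, params)
        sasa_by_atom[cpx] += areas_cpx
        for subset in (rec, lig):
            areas, _ = shrake_rupley_sasa(frame, top, subset, params)
            sasa_by_atom[subset] -= areas
        for atom in cpx:
            acc[pos_in[bucket_of(int(atom))], fk] += (
                params.gamma * sasa_by_atom[atom]
            )
        # beta cancels in the three-species difference only if zero; assign
        # any nonzero beta offset to the ligand bucket for conservation
        acc[pos_in[LIGAND_BUCKET], fk] -= params.beta

    return [
        ResidueContribution(
            residue_id=key,
            series=acc[k].copy(),
            summary=SeriesSummary.from_values(acc[k]),
        )
        for k, key in enumerate(bucket_keys)
    ]


# ---------------------------------------------------------------------------
# breakdown comparison
# ---------------------------------------------------------------------------

def compare_breakdowns(
    a: EnergyBreakdown,
    b: EnergyBreakdown,
    n_resamples: int = 9999,
    seed: int = 0,
    term: str = "dG_bind",
) -> tuple[float, float]:
    """Difference in mean binding energy and a two-sided permutation p-value.

    Frames are pooled and labels permuted ``n_resamples`` times with a
    counter-based RNG (Philox) keyed by ``seed``; the p-value uses the
    add-one convention (1 + #extreme) / (n_resamples + 1).
    """
    x = np.asarray(a.series[term], dtype=float)
    y = np.asarray(b.series[term], dtype=float)
    if x.size < 2 or y.size < 2:
        raise EnergeticsError("both series need at least 2 frames")
    observed = float(y.mean() - x.mean())
    pooled = np.concatenate([x, y])
    rng = np.random.Generator(np.random.Philox(seed))
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        diff = perm[x.size :].mean() - perm[: x.size].mean()
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
    p_value = (1 + count) / (n_resamples + 1)
    return observed, p_value
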