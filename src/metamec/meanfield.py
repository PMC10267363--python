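"""Mean-field MM/PBSA effective energy of the solute.

The per-configuration effective energy replaces the full (hugely
fluctuating) enthalpy of the solvated system:

    U_bar(Q) = U_intra(Q) + G_solv,np(Q) + G_solv,pol(Q)

with U_intra the five intramolecular force-field terms (stretch, bend,
torsion, van der Waals, Coulomb -- consumed as inputs, never computed
here), G_solv,np an empirical per-atom SASA-linear term and G_solv,pol
the electrostatic solvation energy from a finite-difference linearized
Poisson-Boltzmann solve (low-dielectric solute cavity in a
high-dielectric, optionally salted, continuum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COULOMB_KE",
    "SoluteModel",
    "EnergyBreakdown",
    "PBGrid",
    "sphere_points",
    "sasa",
    "g_solv_np",
    "solve_pb",
    "intra_energy",
    "mean_field_energy",
    "energy_delta",
]

#: Coulomb constant, kJ/mol * Angstrom / e^2
COULOMB_KE = 1389.35457644382

#: default per-atom SASA coefficient, kJ/mol/A^2
SIGMA_DEFAULT = 0.0226

INTRA_TERMS = ("u_str", "u_bend", "u_tors", "u_vdw", "u_el")


@dataclass
class SoluteModel:
    """Atoms with coordinates, charges, radii and SASA coefficients."""

    coords: np.ndarray  # (N, 3), Angstrom
    charges: np.ndarray  # elementary charges
    radii: np.ndarray  # Angstrom
    sigmas: np.ndarray | None = None  # kJ/mol/A^2
    names: list[str] | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        n = self.coords.shape[0]
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be an (N, 3) array")
        if self.charges.shape != (n,) or self.radii.shape != (n,):
            raise ValueError("charges and radii must align with coords")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.sigmas is None:
            self.sigmas = np.full(n, SIGMA_DEFAULT)
        else:
            self.sigmas = np.atleast_1d(np.asarray(self.sigmas, float))
            if self.sigmas.shape != (n,):
                raise ValueError("sigmas must align with coords")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class EnergyBreakdown:
    """The seven contributions and their total, all kJ/mol."""

    u_str: float
    u_bend: float
    u_tors: float
    u_vdw: float
    u_el: float
    g_solv_np: float
    g_solv_pol: float

    @property
    def u_intra(self) -> float:
        return self.u_str + self.u_bend + self.u_tors + self.u_vdw + self.u_el

    @property
    def u_bar(self) -> float:
        return self.u_intra + self.g_solv_np + self.g_solv_pol

    def as_dict(self) -> dict[str, float]:
        return {
            "u_str": self.u_str, "u_bend": self.u_bend, "u_tors": self.u_tors,
            "u_vdw": self.u_vdw, "u_el": self.u_el,
            "g_solv_np": self.g_solv_np, "g_solv_pol": self.g_solv_pol,
            "u_bar": self.u_bar,
        }


@dataclass
class PBGrid:
    """Lattice and dielectric settings for the finite-difference PB solve."""

    box_min: np.ndarray
    box_max: np.ndarray
    spacing: float = 0.4  # Angstrom
    eps_in: float = 1.0
    eps_out: float = 80.0
    kappa: float = 0.0  # 1/Angstrom; 0 = pure Poisson
    surface_inflation: float = 0.0  # optional probe inflation of the cavity
    boundary: str = "debye-huckel"

    def __post_init__(self):
        self.box_min = np.asarray(self.box_min, float)
        self.box_max = np.asarray(self.box_max, float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("permittivities must be positive")
        if np.any(self.box_max - self.box_min < 2 * self.spacing):
            raise ValueError("box is degenerate")

    @classmethod
    def around(cls, model: SoluteModel, spacing: float = 0.4,
               margin: float = 8.0, **kw) -> "PBGrid":
        lo = (model.coords - model.radii[:, None]).min(axis=0) - margin
        hi = (model.coords + model.radii[:, None]).max(axis=0) + margin
        return cls(lo, hi, spacing=spacing, **kw)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for d in range(3):
            n = int(math.ceil((self.box_max[d] - self.box_min[d]) / self.spacing)) + 1
            out.append(self.box_min[d] + self.spacing * np.arange(n))
        return tuple(out)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(model: SoluteModel, probe_radius: float = 1.4, n_points: int = 960,
         points: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2.

    Each atom's sphere of radius r_i + probe is sampled at ``n_points``
    fixed quasi-uniform points; a point is accessible when outside every
    neighbour's inflated sphere.  Deterministic for a fixed point set
    (pass ``points`` to co-rotate the sampling sphere with the solute).
    """
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    pts = sphere_points(n_points) if points is None else np.asarray(points, float)
    R = model.radii + probe_radius
    n = model.n_atoms
    out = np.empty(n)
    for i in range(n):
        ri = R[i]
        surface = model.coords[i] + ri * pts
        accessible = np.ones(len(pts), dtype=bool)
        d_atoms = np.linalg.norm(model.coords - model.coords[i], axis=1)
        neighbours = np.nonzero((d_atoms < ri + R) & (np.arange(n) != i))[0]
        for j in neighbours:
            d = np.linalg.norm(surface - model.coords[j], axis=1)
            accessible &= d >= R[j]
            if not accessible.any():
                break
        out[i] = 4.0 * math.pi * ri * ri * accessible.mean()
    return out


def g_solv_np(model: SoluteModel, sasa_values: np.ndarray) -> float:
    """Nonpolar solvation: sum_i sigma_i SASA_i (kJ/mol).

    Positive sigma for hydrophobic groups (burying them is favourable),
    negative for hydrophilic ones.
    """
    sasa_values = np.asarray(sasa_values, float)
    if sasa_values.shape != (model.n_atoms,):
        raise ValueError("sasa values must align with atoms")
    return float(np.dot(model.sigmas, sasa_values))


def _dielectric_nodes(model: SoluteModel, xs, ys, zs, grid: PBGrid) -> np.ndarray:
    """Boolean solute-interior mask on nodes (van der Waals union)."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    inside = np.zeros((nx, ny, nz), dtype=bool)
    h = grid.spacing
    for c, r in zip(model.coords, model.radii + grid.surface_inflation):
        i0 = max(0, int((c[0] - r - xs[0]) / h))
        i1 = min(nx, int((c[0] + r - xs[0]) / h) + 2)
        j0 = max(0, int((c[1] - r - ys[0]) / h))
        j1 = min(ny, int((c[1] + r - ys[0]) / h) + 2)
        k0 = max(0, int((c[2] - r - zs[0]) / h))
        k1 = min(nz, int((c[2] + r - zs[0]) / h) + 2)
        dx = xs[i0:i1] - c[0]
        dy = ys[j0:j1] - c[1]
        dz = zs[k0:k1] - c[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        inside[i0:i1, j0:j1, k0:k1] |= d2 <= r * r
    return inside


def _face_eps(model: SoluteModel, xs, ys, zs, grid: PBGrid,
              n_sub: int = 4) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Harmonic segment-averaged permittivities on cell faces.

    Each internode segment is sampled at ``n_sub`` midpoints; the face
    permittivity is the harmonic mean of the sampled values.  This
    smooths the dielectric boundary consistently with the flux
    discretisation and removes the grid-alignment jitter of a binary
    node assignment.
    """
    h = grid.spacing
    offsets = (np.arange(n_sub) + 0.5) / n_sub * h
    axes = (np.asarray(xs), np.asarray(ys), np.asarray(zs))
    out = []
    for d in range(3):
        shape = [len(ax) for ax in axes]
        shape[d] -= 1
        inv = np.zeros(shape)
        for off in offsets:
            sub_axes = list(axes)
            sub_axes[d] = axes[d][:-1] + off
            inside = _dielectric_nodes(model, *sub_axes, grid)
            inv += np.where(inside, 1.0 / grid.eps_in, 1.0 / grid.eps_out)
        out.append(n_sub / inv)
    return out[0], out[1], out[2]  # shapes (nx-1,ny,nz), (nx,ny-1,nz), (nx,ny,nz-1)


def _assign_charges(model: SoluteModel, xs, ys, zs) -> np.ndarray:
    """Trilinear spread of point charges onto grid nodes (units: e)."""
    h = xs[1] - xs[0]
    q = np.zeros((len(xs), len(ys), len(zs)))
    for c, qq in zip(model.coords, model.charges):
        if qq == 0.0:
            continue
        u = (c - np.array([xs[0], ys[0], zs[0]])) / h
        i, j, k = (int(v) for v in np.floor(u))
        fx, fy, fz = u - np.array([i, j, k])
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    q[i + di, j + dj, k + dk] += qq * wx * wy * wz
    return q


def _boundary_potential(model: SoluteModel, xs, ys, zs, eps: float,
                        kappa: float) -> np.ndarray:
    """Dirichlet boundary values from the Debye-Hueckel superposition."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    phi = np.zeros((nx, ny, nz))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    faces = [
        (0, slice(None), slice(None)), (-1, slice(None), slice(None)),
        (slice(None), 0, slice(None)), (slice(None), -1, slice(None)),
        (slice(None), slice(None), 0), (slice(None), slice(None), -1),
    ]
    for f in faces:
        acc = np.zeros_like(X[f])
        for c, qq in zip(model.coords, model.charges):
            if qq == 0.0:
                continue
            d = np.sqrt((X[f] - c[0]) ** 2 + (Y[f] - c[1]) ** 2 + (Z[f] - c[2]) ** 2)
            d = np.maximum(d, 1e-6)
            acc += COULOMB_KE * qq * np.exp(-kappa * d) / (eps * d)
        phi[f] = acc
    return phi


def _fd_solve(faces: tuple[np.ndarray, np.ndarray, np.ndarray],
              q_nodes: np.ndarray, phi: np.ndarray,
              h: float, kappa2_eps: np.ndarray, tol: float = 1e-6,
              max_iter: int = 20000) -> np.ndarray:
    """Red-black SOR solve of div(eps grad phi) - eps_out k^2 phi = -4 pi ke rho.

    ``phi`` enters holding the Dirichlet boundary values (and an initial
    guess in the interior) and is updated in place.  ``faces`` carries
    the segment-averaged permittivities on the three face orientations.
    """
    eW, eS, eD = faces
    nx, ny, nz = phi.shape

    # interior neighbour-face coefficients
    cW = eW[:-1, 1:-1, 1:-1]
    cE = eW[1:, 1:-1, 1:-1]
    cS = eS[1:-1, :-1, 1:-1]
    cN = eS[1:-1, 1:, 1:-1]
    cD = eD[1:-1, 1:-1, :-1]
    cU = eD[1:-1, 1:-1, 1:]
    diag = cW + cE + cS + cN + cD + cU + kappa2_eps[1:-1, 1:-1, 1:-1] * h * h
    src = 4.0 * math.pi * COULOMB_KE * q_nodes[1:-1, 1:-1, 1:-1] / h

    ii, jj, kk = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1),
                             np.arange(1, nz - 1), indexing="ij")
    parity = (ii + jj + kk) % 2
    masks = (parity == 0, parity == 1)
    omega = 2.0 / (1.0 + math.sin(math.pi / max(nx, ny, nz)))
    src_norm = np.abs(src).sum() + 1e-30

    for it in range(max_iter):
        for mask in masks:
            num = (cW * phi[:-2, 1:-1, 1:-1] + cE * phi[2:, 1:-1, 1:-1]
                   + cS * phi[1:-1, :-2, 1:-1] + cN * phi[1:-1, 2:, 1:-1]
                   + cD * phi[1:-1, 1:-1, :-2] + cU * phi[1:-1, 1:-1, 2:]
                   + src)
            interior = phi[1:-1, 1:-1, 1:-1]
            new = num / diag
            interior[mask] += omega * (new[mask] - interior[mask])
        if it % 20 == 19 or it == max_iter - 1:
            num = (cW * phi[:-2, 1:-1, 1:-1] + cE * phi[2:, 1:-1, 1:-1]
                   + cS * phi[1:-1, :-2, 1:-1] + cN * phi[1:-1, 2:, 1:-1]
                   + cD * phi[1:-1, 1:-1, :-2] + cU * phi[1:-1, 1:-1, 2:]
                   + src)
            resid = np.abs(num - diag * phi[1:-1, 1:-1, 1:-1]).sum()
            if resid <= tol * src_norm:
                return phi
    raise RuntimeError(
        f"PB solve did not converge: relative residual {resid / src_norm:.3e}")


def _interp_phi(phi: np.ndarray, xs, ys, zs, coords: np.ndarray) -> np.ndarray:
    h = xs[1] - xs[0]
    out = np.empty(len(coords))
    for a, c in enumerate(coords):
        u = (c - np.array([xs[0], ys[0], zs[0]])) / h
        i, j, k = (int(v) for v in np.floor(u))
        fx, fy, fz = u - np.array([i, j, k])
        val = 0.0
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    val += wx * wy * wz * phi[i + di, j + dj, k + dk]
        out[a] = val
    return out


def solve_pb(model: SoluteModel, grid: PBGrid, tol: float = 1e-6,
             max_iter: int = 20000) -> float:
    """Polar solvation energy G_solv,pol (kJ/mol) by two FD solves.

    G = 1/2 sum_i q_i [phi_solvated(r_i) - phi_reference(r_i)], where the
    reference solve uses a uniform eps_in dielectric and no salt so the
    lattice self-energy of the spread charges cancels exactly.
    """
    lo = (model.coords - model.radii[:, None]).min(axis=0)
    hi = (model.coords + model.radii[:, None]).max(axis=0)
    if np.any(lo - grid.box_min < 5.0 - 1e-9) or np.any(grid.box_max - hi < 5.0 - 1e-9):
        raise ValueError("solute must sit inside the box with a margin of at least 5 A")
    if not np.any(model.charges):
        return 0.0
    xs, ys, zs = grid.axes()
    h = grid.spacing
    inside = _dielectric_nodes(model, xs, ys, zs, grid)
    q_nodes = _assign_charges(model, xs, ys, zs)

    # solvated solve
    faces = _face_eps(model, xs, ys, zs, grid)
    kappa2_eps = np.where(inside, 0.0, grid.eps_out * grid.kappa ** 2)
    phi_s = _boundary_potential(model, xs, ys, zs, grid.eps_out, grid.kappa)
    phi_s = _initial_guess(model, xs, ys, zs, grid.eps_out, grid.kappa, phi_s)
    phi_s = _fd_solve(faces, q_nodes, phi_s, h, kappa2_eps, tol, max_iter)

    # uniform reference solve (same charge assignment, eps_in everywhere)
    ref_faces = tuple(np.full_like(f, grid.eps_in) for f in faces)
    phi_r = _boundary_potential(model, xs, ys, zs, grid.eps_in, 0.0)
    phi_r = _initial_guess(model, xs, ys, zs, grid.eps_in, 0.0, phi_r)
    phi_r = _fd_solve(ref_faces, q_nodes, phi_r, h, np.zeros_like(kappa2_eps), tol, max_iter)

    dphi = _interp_phi(phi_s - phi_r, xs, ys, zs, model.coords)
    return float(0.5 * np.dot(model.charges, dphi))


def _initial_guess(model: SoluteModel, xs, ys, zs, eps: float, kappa: float,
                   phi: np.ndarray) -> np.ndarray:
    """Fill the interior with the screened-Coulomb superposition.

    A good starting field cuts SOR iterations by a large factor; the
    boundary faces already hold the same values.
    """
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    acc = np.zeros_like(X)
    for c, qq in zip(model.coords, model.charges):
        if qq == 0.0:
            continue
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        d = np.maximum(d, 0.5 * (xs[1] - xs[0]))
        acc += COULOMB_KE * qq * np.exp(-kappa * d) / (eps * d)
    phi[1:-1, 1:-1, 1:-1] = acc[1:-1, 1:-1, 1:-1]
    return phi


def born_energy(q: float, radius: float, eps_in: float = 1.0,
                eps_out: float = 80.0) -> float:
    """Analytic Born solvation energy of a single charged sphere (kJ/mol)."""
    return -COULOMB_KE * q * q / (2.0 * radius) * (1.0 / eps_in - 1.0 / eps_out)


def intra_energy(terms: dict[str, float]) -> float:
    """Sum of the five intramolecular terms (pass-through bookkeeping)."""
    missing = [t for t in INTRA_TERMS if t not in terms]
    if missing:
        raise ValueError(f"missing intramolecular terms: {missing}")
    return float(sum(terms[t] for t in INTRA_TERMS))


def mean_field_energy(terms: dict[str, float], model: SoluteModel, grid: PBGrid,
                      probe_radius: float = 1.4, n_points: int = 960) -> EnergyBreakdown:
    """Assemble the full effective energy breakdown for one configuration."""
    intra_energy(terms)  # validates presence of all five terms
    areas = sasa(model, probe_radius, n_points)
    return EnergyBreakdown(
        u_str=float(terms["u_str"]), u_bend=float(terms["u_bend"]),
        u_tors=float(terms["u_tors"]), u_vdw=float(terms["u_vdw"]),
        u_el=float(terms["u_el"]),
        g_solv_np=g_solv_np(model, areas),
        g_solv_pol=solve_pb(model, grid),
    )


def energy_delta(folded: EnergyBreakdown, unfolded: EnergyBreakdown) -> dict[str, float]:
    """Per-term unfolded - folded differences, plus the total delta."""
    f, u = folded.as_dict(), unfolded.as_dict()
    out = {f"d_{k}": u[k] - f[k] for k in f if k != "u_bar"}
    out["d_u_bar"] = u["u_bar"] - f["u_bar"]
    return out
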