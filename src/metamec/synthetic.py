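"""Synthetic fixtures with known ground truth.

Everything the other modules need for testing is generated here from
explicit seeds: analytic double-well landscapes for the toy sampler,
metastatistics ensembles drawn from a stated discrete proposal with a
known free-energy curve G*(s) (so recovery can be scored exactly), and
toy peptide geometries for the hydrogen-bond CV and the PBSA machinery.

The ensemble generator mirrors the structure of real metastatistics: a
deliberately non-flat, bimodal CV distribution (a sharp folded peak and
a broad unfolded one), per-frame energies that depend on the CV plus
Gaussian noise, and round-robin walker labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .colvar import AtomRecord, HBondPair, Structure
from .meanfield import SoluteModel
from .mec import Metastatistics
from .metadyn import KB, ToySystem

__all__ = [
    "ToyLandscapeSpec",
    "make_double_well",
    "DiscreteProposal",
    "bimodal_proposal",
    "SyntheticEnsembleSpec",
    "sample_metastatistics",
    "exact_free_energy",
    "make_variant_pair",
    "make_toy_peptide",
]


@dataclass(frozen=True)
class ToyLandscapeSpec:
    """A symmetric double well F(s) = h ((s-c)^2/a^2 - 1)^2.

    Minima sit at c +/- a with F = 0; the barrier at s = c has height h.
    An optional linear tilt breaks the symmetry with a known bias.
    """

    barrier: float = 15.0  # kJ/mol
    center: float = 0.0  # CV units
    half_separation: float = 1.5  # CV units
    tilt: float = 0.0  # kJ/mol per CV unit, added as tilt * (s - c)
    temperature: float = 300.0
    friction: float = 10.0
    timestep: float = 0.01
    mass: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")

    @property
    def minima(self) -> tuple[float, float]:
        return (self.center - self.half_separation, self.center + self.half_separation)


def make_double_well(spec: ToyLandscapeSpec) -> ToySystem:
    """Analytic double-well toy system with matching gradient."""
    h, c, a, k = spec.barrier, spec.center, spec.half_separation, spec.tilt

    def F(s: float) -> float:
        u = (s - c) / a
        return h * (u * u - 1.0) ** 2 + k * (s - c)

    def dF(s: float) -> float:
        u = (s - c) / a
        return 4.0 * h * u * (u * u - 1.0) / a + k

    span = 3.0 * a
    return ToySystem(free_energy=F, grad=dF, friction=spec.friction,
                     timestep=spec.timestep, temperature=spec.temperature,
                     mass=spec.mass, domain=(c - span, c + span),
                     s_init=spec.minima[1])


@dataclass(frozen=True)
class DiscreteProposal:
    """A discrete CV proposal P~(xi) on integer-like support."""

    support: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("proposal probabilities must be a distribution")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.support, float), size=n,
                          p=np.asarray(self.probs, float))


def bimodal_proposal(lo_peak: float = 4.0, hi_peak: float = 14.0,
                     lo_width: float = 2.5, hi_width: float = 1.0,
                     hi_weight: float = 0.6, s_max: int = 16) -> DiscreteProposal:
    """Bimodal metastatistics-like proposal on the integers 0..s_max.

    A sharp peak at the folded CV value and a broad one at the unfolded
    value, emulating the CV distribution collected at frozen bias.
    """
    xi = np.arange(s_max + 1, dtype=float)
    p = (1 - hi_weight) * np.exp(-0.5 * ((xi - lo_peak) / lo_width) ** 2) / lo_width \
        + hi_weight * np.exp(-0.5 * ((xi - hi_peak) / hi_width) ** 2) / hi_width
    p /= p.sum()
    return DiscreteProposal(tuple(xi), tuple(p))


@dataclass
class SyntheticEnsembleSpec:
    """Recipe for a metastatistics ensemble with known ground truth.

    ``energy_fn`` maps the CV value to the noiseless mean-field energy
    U(xi) in kJ/mol; per-frame energies add Gaussian noise of width
    ``sigma_E``.  Defaults: 1e5 frames, sigma_E = 2 kJ/mol, 10 walkers.
    """

    proposal: DiscreteProposal = field(default_factory=bimodal_proposal)
    energy_fn: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: (lambda xi: -3.0 * xi))
    sigma_E: float = 2.0
    n_frames: int = 100_000
    n_walkers: int = 10
    T_eff: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 100:
            raise ValueError("need at least 100 frames")
        if self.sigma_E < 0:
            raise ValueError("sigma_E must be non-negative")


def sample_metastatistics(spec: SyntheticEnsembleSpec) -> Metastatistics:
    """Draw frames from the proposal; energies are U(xi) + noise."""
    rng = np.random.default_rng(spec.seed)
    xi = spec.proposal.sample(rng, spec.n_frames)
    energy = np.asarray(spec.energy_fn(xi), float)
    if spec.sigma_E > 0:
        energy = energy + rng.normal(0.0, spec.sigma_E, spec.n_frames)
    walker = np.arange(spec.n_frames) % spec.n_walkers
    time = np.arange(spec.n_frames, dtype=float)
    return Metastatistics(xi, energy, walker=walker, time=time)


def exact_free_energy(spec: SyntheticEnsembleSpec, s_grid: np.ndarray,
                      s0: float) -> np.ndarray:
    """The exact G*(s) - G*(s0) of the generator, computed analytically.

    Works directly on the proposal's discrete distribution (no sampling,
    no shared code with the estimator): for each target s the tilt
    parameter is found by bisection on the closed-form tilted mean, and

        G*(s) = <U>_tilt - T_eff kB (ln Z_tilt + tilt * s).
    """
    xi = np.asarray(spec.proposal.support, float)
    logp = np.log(np.asarray(spec.proposal.probs, float) + 1e-300)
    u = np.asarray(spec.energy_fn(xi), float)

    def g_of(s: float) -> float:
        def tilted_mean(lam: float) -> float:
            w = logp - lam * xi
            w = np.exp(w - w.max())
            return float(np.dot(w, xi) / w.sum())

        a, b = -1.0, 1.0
        while tilted_mean(a) < s:
            a *= 2.0
        while tilted_mean(b) > s:
            b *= 2.0
        for _ in range(200):
            mid = 0.5 * (a + b)
            if tilted_mean(mid) > s:
                a = mid
            else:
                b = mid
        lam = 0.5 * (a + b)
        shift = (logp - lam * xi).max()
        z = np.exp(logp - lam * xi - shift)
        log_z = math.log(z.sum()) + shift
        mean_u = float(np.dot(z, u) / z.sum())
        sc = log_z + lam * s
        return mean_u - spec.T_eff * KB * sc

    s_grid = np.atleast_1d(np.asarray(s_grid, float))
    g0 = g_of(float(s0))
    return np.array([g_of(float(s)) - g0 for s in s_grid])


def make_variant_pair(gap: float, s_folded: float = 14.0, s_unfolded: float = 4.0,
                      base_slope: float = -3.0, seed: int = 0,
                      **kw) -> tuple[SyntheticEnsembleSpec, SyntheticEnsembleSpec]:
    """Reference and variant ensembles with an injected stability gap.

    Both share the proposal (hence the entropic term); the variant's
    energy slope is shifted so that its exact unfolding free energy
    exceeds the reference's by exactly ``gap`` kJ/mol:
    ddG = [G_X(s_unf) - G_X(s_fold)] - [G_0(s_unf) - G_0(s_fold)] = gap.
    """
    if s_folded == s_unfolded:
        raise ValueError("folded and unfolded states must differ")
    slope_shift = gap / (s_unfolded - s_folded)
    ref = SyntheticEnsembleSpec(
        energy_fn=lambda xi: base_slope * xi, seed=seed, **kw)
    var = SyntheticEnsembleSpec(
        energy_fn=lambda xi: (base_slope + slope_shift) * xi, seed=seed + 1, **kw)
    return ref, var


def make_toy_peptide(n_residues: int, geometry: str = "helix",
                     seed: int = 0) -> tuple[Structure, list[HBondPair], SoluteModel]:
    """A backbone-only toy peptide with a matching donor-acceptor list.

    Residue i carries an amide N and a carbonyl O; pair i (i >= 3) bonds
    N(res i) to O(res i-2).  In the ``helix`` geometry every listed pair
    sits well inside the switching radius (~0.8 A, switch value ~1), in
    the ``extended`` geometry at > 8 A (fully broken).  Charges, radii and SASA coefficients carry
    simple documented defaults; deterministic from the seed.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if geometry not in ("helix", "extended"):
        raise ValueError("geometry must be 'helix' or 'extended'")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    aid = 1
    for i in range(1, n_residues + 1):
        o_pos = np.array([3.0 * i, 0.0, 0.0])
        if geometry == "helix":
            n_pos = np.array([3.0 * (i - 2), 0.8, 0.0])
        else:
            n_pos = np.array([3.0 * i, 10.0, 0.0])
        jitter = rng.normal(0.0, 0.01, (2, 3))
        atoms.append(AtomRecord(aid, "N", "GLY", i, "A", n_pos + jitter[0],
                                charge=-0.30, radius=1.55))
        aid += 1
        atoms.append(AtomRecord(aid, "O", "GLY", i, "A", o_pos + jitter[1],
                                charge=-0.40, radius=1.52))
        aid += 1
    pairs = [
        HBondPair((i, "N"), (i - 2, "O"), "beta")
        for i in range(3, n_residues + 1)
    ]
    structure = Structure(atoms)
    model = SoluteModel(
        coords=structure.positions,
        charges=np.array([a.charge for a in atoms]),
        radii=np.array([a.radius for a in atoms]),
    )
    return structure, pairs, model
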