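"""Maximal-constrained-entropy (MEC) reweighting of a metastatistics.

Given the biased ensemble P~ collected under a frozen metadynamics bias,
the MEC method finds the distribution P closest to P~ (maximal cross
entropy, i.e. minimal KL divergence) subject to a constrained mean of
the collective variable, <xi> = s.  The solution is an exponential tilt

    P_g = P~_g exp(-lambda xi_g) / Z_lambda,

with lambda solving <xi>_lambda = s.  At the maximum the cross entropy is
S_c = ln Z_lambda + lambda s (<= 0), and the free energy at target s is

    G(s) = <U>_lambda - T_eff kB S_c(s),

where U is the per-frame mean-field energy (or enthalpy) and T_eff an
effective temperature whose identification with the thermodynamic one is
empirical and therefore always explicit configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .metadyn import KB

__all__ = [
    "Metastatistics",
    "MECSolution",
    "FreeEnergyProfile",
    "metastat_probability",
    "solve_lambda",
    "modulation_weights",
    "cross_entropy_max",
    "constrained_average",
    "free_energy_mec",
    "profile",
    "ddg",
]

#: relative residual tolerance of the lambda solve, in units of range(xi)
LAMBDA_TOL = 1e-10


@dataclass
class Metastatistics:
    """Enumerated frames of the biased ensemble.

    ``xi`` is the CV column the constraint acts on (either the biased CV
    or the extended one, chosen at load time); ``energy`` the per-frame
    mean-field energy in kJ/mol; ``multiplicity`` the number of
    microstates each row stands for (1 for raw trajectory frames,
    arbitrary for pre-aggregated histograms); ``walker`` the source
    walker used by jackknife error estimation.
    """

    xi: np.ndarray
    energy: np.ndarray
    multiplicity: np.ndarray | None = None
    walker: np.ndarray | None = None
    time: np.ndarray | None = None
    xi_prime: np.ndarray | None = None

    def __post_init__(self):
        self.xi = np.asarray(self.xi, float)
        self.energy = np.asarray(self.energy, float)
        n = self.xi.size
        if self.energy.shape != self.xi.shape:
            raise ValueError("energy must align with xi")
        if self.multiplicity is None:
            self.multiplicity = np.ones(n)
        else:
            self.multiplicity = np.asarray(self.multiplicity, float)
            if self.multiplicity.shape != self.xi.shape:
                raise ValueError("multiplicity must align with xi")
            if np.any(self.multiplicity < 0):
                raise ValueError("multiplicities must be non-negative")
        if not np.any(self.multiplicity > 0):
            raise ValueError("multiplicities must not be all zero")
        if self.walker is None:
            self.walker = np.zeros(n, dtype=int)
        else:
            self.walker = np.asarray(self.walker, dtype=int)
            if self.walker.shape != self.xi.shape:
                raise ValueError("walker labels must align with xi")
        if self.xi_prime is not None:
            self.xi_prime = np.asarray(self.xi_prime, float)

    def __len__(self) -> int:
        return self.xi.size

    def subset(self, mask: np.ndarray) -> "Metastatistics":
        return Metastatistics(
            self.xi[mask], self.energy[mask], self.multiplicity[mask],
            self.walker[mask],
            None if self.time is None else self.time[mask],
            None if self.xi_prime is None else self.xi_prime[mask],
        )

    def with_cv(self, column: str) -> "Metastatistics":
        """Return a copy whose constraint column is ``xi`` or ``xi_prime``."""
        if column == "xi":
            return self
        if column == "xi_prime":
            if self.xi_prime is None:
                raise ValueError("this ensemble carries no xi_prime column")
            return Metastatistics(self.xi_prime, self.energy, self.multiplicity,
                                  self.walker, self.time, self.xi)
        raise ValueError("column must be 'xi' or 'xi_prime'")

    @property
    def support(self) -> tuple[float, float]:
        active = self.xi[self.multiplicity > 0]
        return float(active.min()), float(active.max())


def metastat_probability(ms: Metastatistics) -> np.ndarray:
    """P~_g = multiplicity_g / sum multiplicities."""
    return ms.multiplicity / ms.multiplicity.sum()


def _log_p_tilde(ms: Metastatistics) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(ms.multiplicity) - np.log(ms.multiplicity.sum())


def _log_z(ms: Metastatistics, lam: float) -> float:
    return float(logsumexp(_log_p_tilde(ms) - lam * ms.xi))


def _tilted_probability(ms: Metastatistics, lam: float) -> np.ndarray:
    logp = _log_p_tilde(ms) - lam * ms.xi
    logp -= logsumexp(logp)
    return np.exp(logp)


def _mean_xi(ms: Metastatistics, lam: float) -> float:
    return float(np.dot(_tilted_probability(ms, lam), ms.xi))


def solve_lambda(ms: Metastatistics, s_target: float, tol: float = LAMBDA_TOL) -> float:
    """Solve <xi>_lambda = s_target for the tilt parameter lambda.

    <xi>_lambda is strictly decreasing in lambda (its derivative is
    -Var_lambda(xi) < 0), so a bracketed root-find converges globally;
    the initial bracket [-1, 1] is expanded geometrically.
    """
    lo_s, hi_s = ms.support
    if not (lo_s < s_target < hi_s):
        raise ValueError(
            f"target s = {s_target} is outside the open support ({lo_s}, {hi_s}) "
            "and cannot be reached by any tilt")
    if lo_s == hi_s:
        raise ValueError("need at least two distinct xi values")
    span = hi_s - lo_s

    logp_t = _log_p_tilde(ms)
    xi = ms.xi

    def f(lam: float) -> float:
        logp = logp_t - lam * xi
        logp -= logp.max()
        p = np.exp(logp)
        return float(np.dot(p, xi) / p.sum()) - s_target

    f0 = f(0.0)
    if abs(f0) <= tol * span:
        return 0.0
    a, b = -1.0, 1.0
    fa, fb = f(a), f(b)
    for _ in range(200):
        if fa > 0 >= fb or fa >= 0 > fb:
            break
        a *= 2.0
        b *= 2.0
        fa, fb = f(a), f(b)
    else:
        raise RuntimeError("lambda bracket expansion failed")
    lam = brentq(f, a, b, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    if abs(f(lam)) > tol * span:
        raise RuntimeError(
            f"lambda solve did not reach tolerance: residual {f(lam):.3e}")
    return float(lam)


def modulation_weights(ms: Metastatistics, lam: float) -> np.ndarray:
    """Modulated probabilities P_g = P~_g exp(-lambda xi_g)/Z_lambda."""
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    return _tilted_probability(ms, lam)


def cross_entropy_max(ms: Metastatistics, lam: float, s_target: float) -> float:
    """S_c at the maximum: ln Z_lambda + lambda s (the negative KL).

    Raises if lambda does not actually solve the constraint for
    ``s_target``; both closed-form and direct -sum P ln(P/P~) routes agree
    to high precision by construction.
    """
    lo_s, hi_s = ms.support
    if abs(_mean_xi(ms, lam) - s_target) > 1e-7 * (hi_s - lo_s):
        raise ValueError("lambda does not solve the constraint for this target")
    return _log_z(ms, lam) + lam * s_target


def cross_entropy_direct(ms: Metastatistics, lam: float) -> float:
    """-sum_g P_g ln(P_g / P~_g), the definition route (cross-check)."""
    p = _tilted_probability(ms, lam)
    logp_t = _log_p_tilde(ms)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(mask, np.log(np.where(mask, p, 1.0)), 0.0)
    return float(-np.sum(p[mask] * (logp[mask] - logp_t[mask])))


def constrained_average(ms: Metastatistics, lam: float, values: np.ndarray) -> float:
    """b_lambda = sum_g P~_g exp(-lambda xi_g) B_g / Z_lambda."""
    values = np.asarray(values, float)
    if values.shape != ms.xi.shape:
        raise ValueError("per-frame values must align with frames")
    return float(np.dot(_tilted_probability(ms, lam), values))


@dataclass
class MECSolution:
    """All quantities of one constrained solve at target s."""

    s_target: float
    lam: float
    logZ: float
    cross_entropy: float  # S_c, dimensionless, <= 0
    mean_energy: float  # <U>_lambda, kJ/mol
    G: float  # kJ/mol
    T_eff: float  # K


def free_energy_mec(ms: Metastatistics, s_target: float, T_eff: float = 300.0) -> MECSolution:
    """G(s) = <U>_lambda - T_eff kB S_c(s) with lambda from the constraint."""
    lam = solve_lambda(ms, s_target)
    logZ = _log_z(ms, lam)
    sc = logZ + lam * s_target
    mean_u = constrained_average(ms, lam, ms.energy)
    return MECSolution(float(s_target), lam, logZ, sc,
                       mean_u, mean_u - T_eff * KB * sc, T_eff)


@dataclass
class FreeEnergyProfile:
    """G(s) on a target grid, referenced so that G(s0) = 0.

    ``uncertainty`` is the per-point standard error (leave-one-walker-out
    jackknife or walker bootstrap); NaN when not estimated.  ``skipped``
    lists requested targets outside the reachable support.
    """

    s_values: np.ndarray
    G_values: np.ndarray
    s0_reference: float
    uncertainty: np.ndarray | None = None
    lam: np.ndarray | None = None
    cross_entropy: np.ndarray | None = None
    mean_energy: np.ndarray | None = None
    T_eff: float = 300.0
    skipped: list = field(default_factory=list)

    def value_at(self, s: float, atol: float = 1e-8) -> float:
        if self.s_values.size:
            i = np.argmin(np.abs(self.s_values - s))
            if abs(self.s_values[i] - s) <= atol:
                return float(self.G_values[i])
        if abs(s - self.s0_reference) <= atol:
            return 0.0  # the reference point is implicitly on every profile
        raise ValueError(f"s = {s} is not a grid point of this profile")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "s": self.s_values,
            "G": self.G_values,
            "dG_err": np.full_like(self.s_values, np.nan)
            if self.uncertainty is None else self.uncertainty,
            "lambda": np.full_like(self.s_values, np.nan)
            if self.lam is None else self.lam,
            "Sc": np.full_like(self.s_values, np.nan)
            if self.cross_entropy is None else self.cross_entropy,
            "meanU": np.full_like(self.s_values, np.nan)
            if self.mean_energy is None else self.mean_energy,
        })


def _profile_values(ms: Metastatistics, s_grid: np.ndarray, s0: float,
                    T_eff: float) -> np.ndarray:
    g0 = free_energy_mec(ms, s0, T_eff).G
    return np.array([free_energy_mec(ms, s, T_eff).G - g0 for s in s_grid])


def profile(ms: Metastatistics, s_grid: np.ndarray, s0: float,
            T_eff: float = 300.0, errors: str = "jackknife",
            n_boot: int = 0, seed: int = 0) -> FreeEnergyProfile:
    """MEC free-energy profile over a grid of constrained means.

    ``errors``: ``"jackknife"`` (leave one walker out; default),
    ``"bootstrap"`` (resample walkers with replacement, ``n_boot``
    replicates) or ``"none"``.  Unreachable grid points are skipped with
    a warning and recorded in ``skipped``.
    """
    s_grid = np.atleast_1d(np.asarray(s_grid, float))
    lo_s, hi_s = ms.support
    reachable = (s_grid > lo_s) & (s_grid < hi_s)
    if s0 <= lo_s or s0 >= hi_s:
        raise ValueError(f"reference s0 = {s0} is outside the support ({lo_s}, {hi_s})")
    skipped = [float(s) for s in s_grid[~reachable]]
    if skipped:
        warnings.warn(f"skipping unreachable targets: {skipped}")
    grid = s_grid[reachable]

    sols = []
    g0 = free_energy_mec(ms, s0, T_eff)
    for s in grid:
        sols.append(free_energy_mec(ms, s, T_eff))
    G = np.array([sol.G - g0.G for sol in sols])

    err = None
    walkers = np.unique(ms.walker)
    if errors == "jackknife" and walkers.size > 1:
        reps = []
        for w in walkers:
            sub = ms.subset(ms.walker != w)
            try:
                reps.append(_profile_values(sub, grid, s0, T_eff))
            except (ValueError, RuntimeError):
                continue  # walker removal may shrink the support
        if len(reps) > 1:
            reps = np.array(reps)
            n = reps.shape[0]
            err = np.sqrt((n - 1) / n * np.sum((reps - reps.mean(axis=0)) ** 2, axis=0))
    elif errors == "bootstrap" and n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            chosen = rng.choice(walkers, size=walkers.size, replace=True)
            parts = [ms.subset(ms.walker == w) for w in chosen]
            boot = Metastatistics(
                np.concatenate([p.xi for p in parts]),
                np.concatenate([p.energy for p in parts]),
                np.concatenate([p.multiplicity for p in parts]),
                np.concatenate([p.walker for p in parts]),
            )
            try:
                reps.append(_profile_values(boot, grid, s0, T_eff))
            except (ValueError, RuntimeError):
                continue
        if len(reps) > 1:
            err = np.std(np.array(reps), axis=0, ddof=1)
    elif errors not in ("jackknife", "bootstrap", "none"):
        raise ValueError("errors must be 'jackknife', 'bootstrap' or 'none'")

    return FreeEnergyProfile(
        grid, G, float(s0), err,
        lam=np.array([sol.lam for sol in sols]),
        cross_entropy=np.array([sol.cross_entropy for sol in sols]),
        mean_energy=np.array([sol.mean_energy for sol in sols]),
        T_eff=T_eff, skipped=skipped,
    )


def ddg(profile_variant: FreeEnergyProfile, profile_reference: FreeEnergyProfile,
        s_unfolded: float, s_folded: float) -> float:
    """ddG = [G_X(s_unf) - G_X(s_fold)] - [G_0(s_unf) - G_0(s_fold)].

    Positive values mean the variant needs more reversible work to unfold
    than the reference, i.e. the mutation is stabilizing.
    """
    dv = profile_variant.value_at(s_unfolded) - profile_variant.value_at(s_folded)
    dr = profile_reference.value_at(s_unfolded) - profile_reference.value_at(s_folded)
    return dv - dr
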