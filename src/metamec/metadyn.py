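"""Well-tempered metadynamics in collective-variable space.

The bias potential V_G(s, t) is a sum of Gaussians deposited at the
visited CV values.  In the well-tempered variant each new Gaussian is
scaled by exp(-V_G(s, t')/kB dT), so the bias converges to
-dT/(T+dT) * F(s) (up to a constant) and the free-energy difference
between two CV values follows from the frozen bias as

    F(s) - F(s0) = -(T+dT)/dT * [V_G(s) - V_G(s0)].

A swarm of walkers builds the bias cooperatively: every exchange period
each walker's bias is replaced by a convex ("altruistic") combination of
its own bias and the swarm mean, and after the construction stages the
walker biases are averaged into a single frozen bias under which the
metastatistics is collected.

The only dynamics provided here is a desk-scale overdamped Langevin
sampler moving directly in CV space on an analytic landscape; it
exercises the bias bookkeeping, the staging and the reweighting exactly
as a molecular-dynamics engine would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .colvar import CVSeries

__all__ = [
    "KB",
    "GaussianHill",
    "WTParams",
    "BiasGrid",
    "BiasPotential",
    "Stage",
    "Schedule",
    "default_schedule",
    "ToySystem",
    "evaluate_bias",
    "deposit_hill",
    "free_energy_from_bias",
    "altruistic_combine",
    "average_bias_final",
    "interpolate_bias_poly4",
    "Poly4Interpolant",
    "run_toy_walker",
    "reweight_wt",
]

#: Boltzmann constant in kJ/(mol K)
KB = 0.0083144621


@dataclass(frozen=True)
class GaussianHill:
    center: float  # CV units
    width: float  # CV units (delta)
    height: float  # kJ/mol, post-tempering
    deposit_time: float = 0.0  # ps

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("hill width must be positive")
        if self.height <= 0:
            raise ValueError("hill height must be positive")


@dataclass(frozen=True)
class WTParams:
    """Well-tempered deposition parameters.

    ``deltaT`` is the CV-temperature boost; the biasing factor is
    (T + deltaT)/T.  ``tempered=False`` selects the untempered limit in
    which every hill keeps the bare height ``gaussian_height_w``
    (formally deltaT -> infinity).
    """

    T: float = 300.0  # K
    deltaT: float = 5700.0  # K
    gaussian_height_w: float = 1.0  # kJ/mol
    gaussian_width_delta: float = 1.0  # CV units
    tau_G: float = 20.0  # ps between deposits
    tempered: bool = True

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.deltaT < 0:
            raise ValueError("deltaT must be non-negative")
        if self.gaussian_height_w <= 0 or self.gaussian_width_delta <= 0:
            raise ValueError("hill height and width must be positive")
        if self.tau_G <= 0:
            raise ValueError("tau_G must be positive")

    @property
    def biasing_factor(self) -> float:
        return (self.T + self.deltaT) / self.T

    @classmethod
    def from_biasing_factor(cls, T: float, biasing_factor: float, **kw) -> "WTParams":
        if biasing_factor <= 1:
            raise ValueError("biasing factor must exceed 1")
        return cls(T=T, deltaT=(biasing_factor - 1.0) * T, **kw)


@dataclass
class BiasGrid:
    """Uniformly spaced tabulation of a bias (kJ/mol) on CV nodes."""

    nodes: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.values = np.asarray(self.values, float)
        if self.nodes.ndim != 1 or self.nodes.size < 2:
            raise ValueError("need at least two grid nodes")
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        if self.nodes.shape != self.values.shape or not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite and align with nodes")

    @property
    def spacing(self) -> float:
        return float(self.nodes[1] - self.nodes[0])

    def __call__(self, s):
        # constant continuation outside the tabulated range
        return np.interp(s, self.nodes, self.values)

    def derivative(self, s):
        dv = np.gradient(self.values, self.nodes)
        return np.interp(s, self.nodes, dv)


class BiasPotential:
    """Sum of deposited Gaussian hills on top of an optional base grid.

    The base grid carries bias inherited from altruistic combination or
    averaging steps (where per-hill identity is lost); freshly deposited
    hills live in ``hills``.  ``additive_offset`` is the physically
    irrelevant constant.
    """

    def __init__(self, hills: Sequence[GaussianHill] = (),
                 base: BiasGrid | None = None,
                 additive_offset: float = 0.0):
        self.hills: list[GaussianHill] = list(hills)
        self.base = base
        self.additive_offset = float(additive_offset)
        self._centers = np.array([h.center for h in self.hills])
        self._widths = np.array([h.width for h in self.hills])
        self._heights = np.array([h.height for h in self.hills])

    def copy(self) -> "BiasPotential":
        base = BiasGrid(self.base.nodes.copy(), self.base.values.copy()) if self.base else None
        return BiasPotential(list(self.hills), base, self.additive_offset)

    def add_hill(self, hill: GaussianHill) -> None:
        self.hills.append(hill)
        self._centers = np.append(self._centers, hill.center)
        self._widths = np.append(self._widths, hill.width)
        self._heights = np.append(self._heights, hill.height)

    def __call__(self, s):
        return evaluate_bias(self, s)

    def gradient(self, s):
        s_arr = np.atleast_1d(np.asarray(s, float))
        out = np.zeros_like(s_arr)
        if self.hills:
            d = s_arr[:, None] - self._centers[None, :]
            g = self._heights[None, :] * np.exp(-0.5 * (d / self._widths[None, :]) ** 2)
            out += (-d / self._widths[None, :] ** 2 * g).sum(axis=1)
        if self.base is not None:
            out += self.base.derivative(s_arr)
        return float(out[0]) if np.isscalar(s) or np.ndim(s) == 0 else out

    def to_grid(self, lo: float, hi: float, spacing: float = 0.1) -> BiasGrid:
        n = int(round((hi - lo) / spacing)) + 1
        nodes = lo + spacing * np.arange(n)
        return BiasGrid(nodes, np.asarray(self(nodes), float))


def evaluate_bias(b: BiasPotential, s):
    """V_G(s): Gaussian hills + base grid + additive offset."""
    s_arr = np.atleast_1d(np.asarray(s, float))
    out = np.full_like(s_arr, b.additive_offset)
    if b.hills:
        d = s_arr[:, None] - b._centers[None, :]
        out += (b._heights[None, :] * np.exp(-0.5 * (d / b._widths[None, :]) ** 2)).sum(axis=1)
    if b.base is not None:
        out += b.base(s_arr)
    return float(out[0]) if np.ndim(s) == 0 else out


def deposit_hill(b: BiasPotential, s_now: float, p: WTParams, t: float = 0.0) -> BiasPotential:
    """Append one hill at the current CV value (mutates and returns ``b``).

    Well-tempered height: w * exp(-V_G(s_now, t)/(kB deltaT)); untempered
    runs (``p.tempered`` false) keep the bare height w.
    """
    if p.tempered:
        if p.deltaT == 0:
            raise ValueError("deltaT = 0 is incompatible with tempered deposition")
        height = p.gaussian_height_w * math.exp(
            -float(evaluate_bias(b, s_now)) / (KB * p.deltaT))
    else:
        height = p.gaussian_height_w
    b.add_hill(GaussianHill(float(s_now), p.gaussian_width_delta, height, t))
    return b


def free_energy_from_bias(b: BiasPotential | BiasGrid | Callable, p: WTParams,
                          s, s0: float):
    """F(s) - F(s0) = -(T+dT)/dT * (V_G(s) - V_G(s0)); offset-independent."""
    if p.deltaT <= 0:
        raise ValueError("deltaT must be positive to convert bias to free energy")
    prefactor = (p.T + p.deltaT) / p.deltaT
    v = b(s) if callable(b) else evaluate_bias(b, s)
    v0 = b(s0) if callable(b) else evaluate_bias(b, s0)
    return -prefactor * (np.asarray(v, float) - float(v0)) if np.ndim(s) else \
        -prefactor * (float(v) - float(v0))


def _shared_nodes(biases: Sequence[BiasPotential], spacing: float) -> np.ndarray:
    los, his = [], []
    for b in biases:
        pts = []
        if b.base is not None:
            pts += [b.base.nodes[0], b.base.nodes[-1]]
        if b.hills:
            pts += [b._centers.min() - 4 * b._widths.max(),
                    b._centers.max() + 4 * b._widths.max()]
        if not pts:
            pts = [0.0, 1.0]
        los.append(min(pts))
        his.append(max(pts))
    lo, hi = min(los), max(his)
    n = max(2, int(math.ceil((hi - lo) / spacing)) + 1)
    return lo + spacing * np.arange(n)


def altruistic_combine(biases: Sequence[BiasPotential], alpha: float, w_share: float,
                       spacing: float = 0.1,
                       rule: Callable[[np.ndarray, np.ndarray, float, float], np.ndarray] | None = None,
                       ) -> list[BiasPotential]:
    """Mix each walker's bias with the swarm: the altruistic exchange.

    Default rule: V_i' = (1-alpha) V_i + alpha [w V_i + (1-w) mean_j V_j].
    ``alpha = 0`` leaves every bias untouched; the rule is pluggable via
    ``rule(V_i, V_mean, alpha, w_share) -> V_i'`` acting on grid values.
    """
    biases = list(biases)
    if not biases:
        raise ValueError("need at least one walker bias")
    if not (0 <= alpha <= 1 and 0 <= w_share <= 1):
        raise ValueError("alpha and w_share must lie in [0, 1]")
    if alpha == 0:
        return [b.copy() for b in biases]
    nodes = _shared_nodes(biases, spacing)
    values = np.array([np.asarray(evaluate_bias(b, nodes), float) for b in biases])
    mean = values.mean(axis=0)
    if rule is None:
        def rule(v, m, a, w):
            return (1 - a) * v + a * (w * v + (1 - w) * m)
    return [BiasPotential(base=BiasGrid(nodes, rule(v, mean, alpha, w_share)))
            for v in values]


def average_bias_final(biases: Sequence[BiasPotential], spacing: float = 0.1) -> BiasPotential:
    """Pointwise mean of the walker biases on a shared grid.

    Used after the last construction stage to hand every walker the same
    frozen bias for metastatistics collection.
    """
    biases = list(biases)
    if not biases:
        raise ValueError("need at least one walker bias")
    nodes = _shared_nodes(biases, spacing)
    values = np.array([np.asarray(evaluate_bias(b, nodes), float) for b in biases])
    return BiasPotential(base=BiasGrid(nodes, values.mean(axis=0)))


@dataclass
class Poly4Interpolant:
    """Degree-4 least-squares fit on a range, linear C1 continuation outside."""

    coeffs: np.ndarray  # ascending powers
    fit_range: tuple[float, float]

    def __call__(self, s):
        s_arr = np.atleast_1d(np.asarray(s, float))
        lo, hi = self.fit_range
        poly = np.polynomial.polynomial.Polynomial(self.coeffs)
        dpoly = poly.deriv()
        out = poly(s_arr)
        left = s_arr < lo
        right = s_arr > hi
        out[left] = poly(lo) + dpoly(lo) * (s_arr[left] - lo)
        out[right] = poly(hi) + dpoly(hi) * (s_arr[right] - hi)
        return float(out[0]) if np.ndim(s) == 0 else out


def interpolate_bias_poly4(grid: BiasGrid, fit_range: tuple[float, float]) -> Poly4Interpolant:
    """Smooth a tabulated bias with a quartic fit inside ``fit_range``.

    Outside the range the interpolant continues linearly with the slope of
    the quartic at the boundary (continuous value and derivative).
    """
    lo, hi = fit_range
    mask = (grid.nodes >= lo) & (grid.nodes <= hi)
    if mask.sum() < 5:
        raise ValueError("need at least 5 grid nodes inside the fit range")
    coeffs = np.polynomial.polynomial.polyfit(grid.nodes[mask], grid.values[mask], 4)
    return Poly4Interpolant(coeffs, (float(lo), float(hi)))


@dataclass(frozen=True)
class Stage:
    label: str
    duration_ns: float
    alpha: float | None = None
    w_share: float | None = None
    bias_updated: bool = False

    def __post_init__(self):
        if self.duration_ns <= 0:
            raise ValueError("stage duration must be positive")
        for v in (self.alpha, self.w_share):
            if v is not None and not (0 <= v <= 1):
                raise ValueError("alpha and w_share must lie in [0, 1]")


@dataclass
class Schedule:
    """Ordered simulation stages: equilibration, bias construction, collection.

    Construction stages carry the altruistic (alpha, w_share) used to mix
    walker biases at the end of each exchange period; collection stages
    run with the bias frozen.
    """

    stages: list[Stage]
    exchange_ns: float = 2.0  # altruistic exchange period within a stage

    @property
    def construction_ns(self) -> float:
        """Total time during which the bias is updated."""
        return sum(st.duration_ns for st in self.stages if st.bias_updated)

    @property
    def equilibration_ns(self) -> float:
        out = 0.0
        for st in self.stages:
            if st.bias_updated:
                break
            out += st.duration_ns
        return out

    @property
    def collection_ns(self) -> float:
        out = 0.0
        seen_update = False
        for st in self.stages:
            if st.bias_updated:
                seen_update = True
            elif seen_update:
                out += st.duration_ns
        return out

    @property
    def pre_collection_ns(self) -> float:
        """Elapsed time through the last bias-construction stage."""
        return self.equilibration_ns + self.construction_ns


def default_schedule(collection_ns: float = 10.0) -> Schedule:
    """The production staging: 8 ns equilibration, 22 ns altruistic
    construction with ramping alpha, then collection at frozen bias."""
    stages = [
        Stage("1-4", 8.0, None, None, False),
        Stage("5", 2.0, 0.0, 1.0, True),
        Stage("6", 2.0, 0.25, 1.0, True),
        Stage("7", 2.0, 0.5, 1.0, True),
        Stage("8", 2.0, 0.75, 1.0, True),
        Stage("9-15", 14.0, 1.0, 0.5, True),
        Stage("16-end", collection_ns, None, None, False),
    ]
    return Schedule(stages)


@dataclass
class ToySystem:
    """Overdamped Langevin dynamics directly on the CV coordinate.

    The mobility is 1/(mass * friction); the diffusion constant follows
    from Einstein's relation D = kB T / (mass * friction).
    """

    free_energy: Callable[[float], float]  # kJ/mol
    grad: Callable[[float], float]  # dF/ds
    friction: float = 10.0  # 1/ps
    timestep: float = 0.01  # ps
    temperature: float = 300.0  # K
    mass: float = 1.0  # CV-units^2 kJ/mol ps^-2 consistent effective mass
    domain: tuple[float, float] = (-5.0, 5.0)
    s_init: float = 0.0

    def __post_init__(self):
        if self.timestep <= 0 or self.friction <= 0 or self.mass <= 0:
            raise ValueError("timestep, friction and mass must be positive")

    @property
    def mobility(self) -> float:
        return 1.0 / (self.mass * self.friction)


def _sample_grid(sys: ToySystem, spacing: float) -> np.ndarray:
    lo, hi = sys.domain
    n = int(math.ceil((hi - lo) / spacing)) + 1
    return lo + spacing * np.arange(n)


def run_toy_walker(sys: ToySystem, p: WTParams, schedule: Schedule,
                   n_walkers: int = 1, seed: int = 0,
                   sample_stride_ps: float = 1.0,
                   grid_spacing: float = 0.1,
                   ns_to_ps: float = 1000.0,
                   ) -> tuple[list[CVSeries], BiasPotential, list[BiasPotential]]:
    """Run the staged multi-walker well-tempered toy simulation.

    Returns ``(series, final_bias, walker_biases)``: one CV series per
    walker collected during the frozen-bias stages, the averaged final
    bias, and the per-walker biases at the end of construction.  Fully
    deterministic for a given seed.  ``ns_to_ps`` converts schedule
    durations to sampler time (set to 1 to read stage durations as ps).
    """
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    rng = np.random.default_rng(seed)
    dt = sys.timestep
    mob = sys.mobility
    noise_sigma = math.sqrt(2.0 * KB * sys.temperature * mob * dt)
    nodes = _sample_grid(sys, grid_spacing)
    lo, hi = float(nodes[0]), float(nodes[-1])
    inv_h = 1.0 / grid_spacing
    n_nodes = nodes.size
    dF_nodes = np.array([sys.grad(x) for x in nodes], float)

    deposit_every = max(1, int(round(p.tau_G / dt)))
    stride_every = max(1, int(round(sample_stride_ps / dt)))

    s = np.full(n_walkers, float(sys.s_init))
    biases = [BiasPotential() for _ in range(n_walkers)]
    # cached total drift grid per walker: dF + dV_G
    grad_grids = [dF_nodes.copy() for _ in range(n_walkers)]
    times: list[list[float]] = [[] for _ in range(n_walkers)]
    values: list[list[float]] = [[] for _ in range(n_walkers)]
    t_now = 0.0
    frozen = None  # averaged final bias once construction ends
    seen_update = False

    def add_hill_to_cache(k: int, hill: GaussianHill) -> None:
        d = nodes - hill.center
        g = hill.height * np.exp(-0.5 * (d / hill.width) ** 2)
        grad_grids[k] += -d / hill.width ** 2 * g

    def rebuild_cache(k: int) -> None:
        grad_grids[k] = dF_nodes + np.asarray(biases[k].gradient(nodes), float)

    for st in schedule.stages:
        duration_ps = st.duration_ns * ns_to_ps
        if st.bias_updated:
            seen_update = True
        collecting = (not st.bias_updated) and seen_update
        if collecting and frozen is None:
            frozen = average_bias_final(biases, grid_spacing)
            for k in range(n_walkers):
                biases[k] = frozen.copy()
                rebuild_cache(k)
        exchange_ps = schedule.exchange_ns * ns_to_ps if st.bias_updated else duration_ps
        n_blocks = max(1, int(round(duration_ps / exchange_ps)))
        block_steps = int(round(duration_ps / n_blocks / dt))
        for _ in range(n_blocks):
            noise = rng.standard_normal((block_steps, n_walkers)) * noise_sigma
            for step in range(block_steps):
                for k in range(n_walkers):
                    sk = s[k]
                    u = (sk - lo) * inv_h
                    i = int(u)
                    if i < 0:
                        i, frac = 0, 0.0
                    elif i >= n_nodes - 1:
                        i, frac = n_nodes - 2, 1.0
                    else:
                        frac = u - i
                    gg = grad_grids[k]
                    drift = gg[i] * (1.0 - frac) + gg[i + 1] * frac
                    sk = sk - mob * drift * dt + noise[step, k]
                    if not (-1e6 < sk < 1e6):
                        raise RuntimeError(
                            f"toy integration diverged: walker {k}, s = {sk}")
                    # reflect at the domain edges to keep the grid valid
                    if sk < lo:
                        sk = 2 * lo - sk
                    elif sk > hi:
                        sk = 2 * hi - sk
                    s[k] = sk
                t_now += dt
                step_index = int(round(t_now / dt))
                if st.bias_updated and step_index % deposit_every == 0:
                    for k in range(n_walkers):
                        b = biases[k]
                        deposit_hill(b, s[k], p, t_now)
                        add_hill_to_cache(k, b.hills[-1])
                if collecting and step_index % stride_every == 0:
                    for k in range(n_walkers):
                        times[k].append(t_now)
                        values[k].append(s[k])
            if st.bias_updated and n_walkers > 1:
                biases = altruistic_combine(biases, st.alpha or 0.0,
                                            st.w_share if st.w_share is not None else 1.0,
                                            grid_spacing)
                for k in range(n_walkers):
                    rebuild_cache(k)
    if frozen is None:
        frozen = average_bias_final(biases, grid_spacing)
    series = [CVSeries(np.array(times[k]), np.array(values[k]), walker=k)
              for k in range(n_walkers)]
    return series, frozen, biases


def reweight_wt(series: CVSeries | np.ndarray, b: BiasPotential | BiasGrid | Callable,
                p: WTParams, observable: np.ndarray | None = None):
    """Unbias frame averages collected under a frozen bias.

    Weights are proportional to exp(+V_G(s)/kB T), max-shifted before
    exponentiation.  With ``observable=None`` the normalised weights are
    returned; otherwise the weighted average of the observable.
    """
    xi = series.xi if isinstance(series, CVSeries) else np.asarray(series, float)
    v = b(xi) if callable(b) else evaluate_bias(b, xi)
    logw = np.asarray(v, float) / (KB * p.T)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    if observable is None:
        return w
    observable = np.asarray(observable, float)
    if observable.shape != xi.shape:
        raise ValueError("observable must align with frames")
    return float(np.dot(w, observable))
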