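"""End-to-end ddG workflow.

For each sequence variant the pipeline ingests a metastatistics
ensemble, locates the folded and unfolded states from the CV
distribution (or takes them from configuration), runs constrained
free-energy profiles on a shared grid, and reports

    ddG = [G_X(s_unf) - G_X(s_fold)] - [G_0(s_unf) - G_0(s_fold)],

positive meaning the mutation is stabilizing.  Two routes are always
reported when a bias grid is supplied: the direct metadynamics estimate
(from the frozen bias) and the entropy-constrained (MEC) estimate; the
two can legitimately disagree when the biased CV misses slow degrees of
freedom, which is precisely what the extended-CV MEC analysis corrects.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .mec import FreeEnergyProfile, Metastatistics, ddg, profile
from .metadyn import BiasGrid, Poly4Interpolant, WTParams, free_energy_from_bias

__all__ = [
    "VariantSpec",
    "DDGReport",
    "select_states",
    "run_pipeline",
    "fes_direct",
]


@dataclass(frozen=True)
class VariantSpec:
    """One sequence in a run: the reference (wild type) or a variant."""

    name: str
    ensemble_path: str
    role: str = "variant"  # "reference" | "variant"

    def __post_init__(self):
        if self.role not in ("reference", "variant"):
            raise ValueError("role must be 'reference' or 'variant'")


@dataclass
class DDGReport:
    """Per-variant outcome of the pipeline."""

    name: str
    profile: FreeEnergyProfile
    s_folded: float
    s_unfolded: float
    ddg: float  # kJ/mol, MEC route
    sign_prediction: str  # "stabilizing" | "destabilizing" | "neutral"
    ddg_direct: float | None = None  # metadynamics-only route, if bias given
    energy_deltas: dict[str, float] | None = None

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "s_folded": self.s_folded,
            "s_unfolded": self.s_unfolded,
            "ddg_kJmol": self.ddg,
            "ddg_direct_kJmol": self.ddg_direct,
            "sign_prediction": self.sign_prediction,
            "energy_deltas": self.energy_deltas,
            "profile": {
                "s": self.profile.s_values.tolist(),
                "G": self.profile.G_values.tolist(),
                "dG_err": None if self.profile.uncertainty is None
                else self.profile.uncertainty.tolist(),
            },
        }


def _smooth(p: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return p
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.r_[np.full(pad, p[0]), p, np.full(pad, p[-1])]
    return np.convolve(padded, kernel, mode="valid")[: p.size]


def select_states(dist: np.ndarray, centers: np.ndarray,
                  min_gap: float = 5.0, smooth_window: int = 3,
                  ) -> tuple[float, float]:
    """Pick (s_folded, s_unfolded) from a normalised CV histogram.

    The folded state is the location of the highest peak after a small
    moving-average smoothing; the unfolded state is the highest remaining
    local maximum at least ``min_gap`` CV units away.  Ties break toward
    lower s.  A histogram with fewer than two separated maxima raises,
    instructing manual state specification.
    """
    dist = np.asarray(dist, float)
    centers = np.asarray(centers, float)
    if dist.shape != centers.shape:
        raise ValueError("distribution and bin centers must align")
    p = _smooth(dist, smooth_window)
    ext = np.r_[-np.inf, p, -np.inf]
    is_peak = (p >= ext[:-2]) & (p >= ext[2:]) & (p > 0)
    # collapse plateaus: keep the lowest-s bin of any run of equal maxima
    peaks = [i for i in np.nonzero(is_peak)[0] if i == 0 or not is_peak[i - 1] or p[i] != p[i - 1]]
    if not peaks:
        raise ValueError("no local maxima in the CV distribution")
    # highest peak; ties toward lower s (stable because peaks are s-ordered)
    folded_i = max(peaks, key=lambda i: (p[i], -centers[i]))
    candidates = [i for i in peaks if abs(centers[i] - centers[folded_i]) >= min_gap]
    if not candidates:
        raise ValueError(
            "CV distribution looks unimodal at this separation gap; "
            "specify the folded/unfolded states manually")
    unfolded_i = max(candidates, key=lambda i: (p[i], -centers[i]))
    return float(centers[folded_i]), float(centers[unfolded_i])


def fes_direct(bias_grid: BiasGrid | Poly4Interpolant, wt_params: WTParams,
               s: float, s0: float) -> float:
    """Direct metadynamics free-energy change between two CV values.

    Uses the frozen bias grid (or its quartic interpolant) and the
    well-tempered bias-to-free-energy relation.
    """
    if isinstance(bias_grid, BiasGrid):
        lo, hi = bias_grid.nodes[0], bias_grid.nodes[-1]
        for v in (s, s0):
            if not (lo <= v <= hi):
                raise ValueError(f"s = {v} is outside the bias grid [{lo}, {hi}]")
    return float(free_energy_from_bias(bias_grid, wt_params, s, s0))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _term_deltas(ms: Metastatistics, term_values: dict[str, np.ndarray],
                 s_folded: float, s_unfolded: float) -> dict[str, float]:
    from .mec import constrained_average, solve_lambda

    lam_f = solve_lambda(ms, s_folded)
    lam_u = solve_lambda(ms, s_unfolded)
    out = {}
    total = 0.0
    for term, values in term_values.items():
        d = constrained_average(ms, lam_u, values) - constrained_average(ms, lam_f, values)
        out[f"d_{term}"] = d
        total += d
    out["d_u_bar"] = total
    return out


def run_pipeline(config: dict) -> dict:
    """Run the full ddG workflow from a configuration mapping.

    Config keys: ``variants`` (list of dicts with name/ensemble/role),
    ``cv`` ("xi" | "xi_prime"), ``T_eff``, ``s_grid`` (list or
    "lo:hi:step" string), ``s_folded``/``s_unfolded`` (optional state
    override), ``min_gap``, ``errors`` ("jackknife"/"bootstrap"/"none"),
    ``seed``, optional ``bias_grid`` path + ``biasing_factor`` for the
    direct route, optional ``term_columns`` naming per-frame energy-term
    columns for the per-term decomposition.

    Returns a JSON-serialisable report with a manifest (inputs, hashes,
    tolerances, seed); identical inputs and seed give identical bytes.
    """
    cv = config.get("cv", "xi")
    T_eff = float(config.get("T_eff", 300.0))
    errors = config.get("errors", "jackknife")
    seed = int(config.get("seed", 0))
    min_gap = float(config.get("min_gap", 5.0))

    specs = [VariantSpec(v["name"], v["ensemble"], v.get("role", "variant"))
             for v in config["variants"]]
    refs = [v for v in specs if v.role == "reference"]
    if len(refs) != 1:
        raise ValueError("exactly one variant must have role 'reference'")
    reference = refs[0]

    ensembles: dict[str, Metastatistics] = {}
    for v in specs:
        ensembles[v.name] = mio.read_ensemble(v.ensemble_path, cv=cv)

    # states: user override or detected from the reference distribution
    if "s_folded" in config and "s_unfolded" in config:
        s_folded = float(config["s_folded"])
        s_unfolded = float(config["s_unfolded"])
    else:
        ms0 = ensembles[reference.name]
        lo, hi = ms0.support
        edges = np.arange(np.floor(lo) - 0.5, np.ceil(hi) + 1.5)
        counts, _ = np.histogram(ms0.xi, bins=edges)
        dist = counts / counts.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
        s_folded, s_unfolded = select_states(dist, centers, min_gap=min_gap)

    sg = config.get("s_grid")
    if sg is None:
        s_grid = np.array(sorted({s_folded, s_unfolded}), float)
    elif isinstance(sg, str):
        lo, hi, step = (float(x) for x in sg.split(":"))
        s_grid = np.arange(lo, hi + 0.5 * step, step)
    else:
        s_grid = np.asarray(sg, float)
    for needed in (s_folded, s_unfolded):
        if not np.any(np.isclose(s_grid, needed)):
            s_grid = np.sort(np.append(s_grid, needed))

    bias = None
    wtp = None
    if "bias_grid" in config:
        bias, meta = mio.read_bias_grid(config["bias_grid"])
        T = float(meta.get("T", config.get("T", 300.0)))
        dT = float(meta.get("deltaT", (float(config.get("biasing_factor", 20.0)) - 1) * T))
        wtp = WTParams(T=T, deltaT=dT)

    profiles: dict[str, FreeEnergyProfile] = {}
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in specs:
            profiles[v.name] = profile(ensembles[v.name], s_grid, s0=s_folded,
                                       T_eff=T_eff, errors=errors, seed=seed)
    ref_profile = profiles[reference.name]

    term_cols = config.get("term_columns", [])
    for v in specs:
        if v.role == "reference":
            continue
        value = ddg(profiles[v.name], ref_profile, s_unfolded, s_folded)
        if value > 0:
            sign = "stabilizing"
        elif value < 0:
            sign = "destabilizing"
        else:
            sign = "neutral"
        direct = None
        if bias is not None:
            direct = fes_direct(bias, wtp, s_unfolded, s_folded)
        deltas = None
        if term_cols:
            import pandas as pd

            df = mio._read_fields_table(v.ensemble_path)
            deltas = _term_deltas(
                ensembles[v.name],
                {c: df[c].to_numpy() for c in term_cols},
                s_folded, s_unfolded)
        reports.append(DDGReport(v.name, profiles[v.name], s_folded, s_unfolded,
                                 value, sign, direct, deltas))

    manifest = {
        "reference": reference.name,
        "cv": cv,
        "T_eff": T_eff,
        "errors": errors,
        "seed": seed,
        "s_folded": s_folded,
        "s_unfolded": s_unfolded,
        "s_grid": s_grid.tolist(),
        "lambda_tolerance": 1e-10,
        "inputs": {v.name: _sha256(v.ensemble_path) for v in specs},
    }
    return {
        "manifest": manifest,
        "reference_profile": {
            "s": ref_profile.s_values.tolist(),
            "G": ref_profile.G_values.tolist(),
        },
        "variants": [r.as_dict() for r in reports],
    }


def report_to_json(report: dict, path: str | Path) -> None:
    """Serialise a pipeline report deterministically."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
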