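"""Readers and writers for the text formats the toolkit speaks.

All tables are whitespace-separated text: COLVAR-style CV series and
ensemble tables with a ``#! FIELDS ...`` header line, HILLS-style hill
logs, two-column bias grids, TSV pair lists, and PQR atom records.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .colvar import AtomRecord, CVSeries, HBondPair, Structure
from .meanfield import SIGMA_DEFAULT, SoluteModel
from .mec import Metastatistics
from .metadyn import BiasGrid, BiasPotential, GaussianHill, Schedule, Stage, WTParams

__all__ = [
    "read_pairs", "write_pairs", "bpti_hbond_pairs",
    "read_colvar", "write_colvar",
    "read_hills", "write_hills",
    "read_bias_grid", "write_bias_grid",
    "read_ensemble", "write_ensemble",
    "read_pqr", "write_pdb",
    "read_schedule", "write_schedule",
]


def _read_fields_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#!"):
        raise ValueError(f"{path}: missing '#! FIELDS ...' header")
    cols = first.split()[2:]
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=cols)
    return df


def _write_fields_table(path: str | Path, df: pd.DataFrame, comments: list[str] = ()):
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        for c in comments:
            fh.write(f"#! SET {c}\n")
        df.to_csv(fh, sep=" ", header=False, index=False, float_format="%.10g")


# -- pair lists ---------------------------------------------------------------

def read_pairs(path: str | Path) -> list[HBondPair]:
    df = pd.read_csv(path, sep="\t")
    required = {"group", "donor_resnum", "donor_atom", "acceptor_resnum", "acceptor_atom"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair list must have columns {sorted(required)}")
    return [
        HBondPair((int(r.donor_resnum), str(r.donor_atom)),
                  (int(r.acceptor_resnum), str(r.acceptor_atom)), str(r.group))
        for r in df.itertuples()
    ]


def write_pairs(pairs: list[HBondPair], path: str | Path) -> None:
    rows = [{
        "group": p.group,
        "donor_resnum": p.donor_selector[0], "donor_atom": p.donor_selector[1],
        "acceptor_resnum": p.acceptor_selector[0], "acceptor_atom": p.acceptor_selector[1],
    } for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bpti_hbond_pairs() -> list[HBondPair]:
    """The packaged native BPTI donor-acceptor list (8 beta + 3 alpha1 + 5 alpha2)."""
    ref = importlib.resources.files("metamec") / "data" / "bpti_pairs.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_pairs(p)


# -- CV series ----------------------------------------------------------------

def read_colvar(path: str | Path) -> CVSeries:
    df = _read_fields_table(path)
    if "time" not in df or "xi" not in df:
        raise ValueError("COLVAR table needs at least 'time' and 'xi' columns")
    return CVSeries(df["time"].to_numpy(), df["xi"].to_numpy(),
                    df["xi_prime"].to_numpy() if "xi_prime" in df else None)


def write_colvar(series: CVSeries, path: str | Path) -> None:
    data = {"time": series.times, "xi": series.xi}
    if series.xi_prime is not None:
        data["xi_prime"] = series.xi_prime
    _write_fields_table(path, pd.DataFrame(data))


# -- hills and bias grids -----------------------------------------------------

def read_hills(path: str | Path) -> BiasPotential:
    df = _read_fields_table(path)
    hills = [GaussianHill(r.center, r.sigma, r.height, r.time) for r in df.itertuples()]
    return BiasPotential(hills)


def write_hills(b: BiasPotential, path: str | Path, p: WTParams | None = None) -> None:
    biasf = p.biasing_factor if p is not None else float("nan")
    df = pd.DataFrame({
        "time": [h.deposit_time for h in b.hills],
        "center": [h.center for h in b.hills],
        "sigma": [h.width for h in b.hills],
        "height": [h.height for h in b.hills],
        "biasf": biasf,
    })
    _write_fields_table(path, df)


def read_bias_grid(path: str | Path) -> tuple[BiasGrid, dict[str, float]]:
    meta: dict[str, float] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#! ").split()
            if len(parts) >= 3 and parts[0] == "SET":
                meta[parts[1]] = float(parts[2])
            continue
        rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: bias grid must be two columns (s, V_G)")
    return BiasGrid(arr[:, 0], arr[:, 1]), meta


def write_bias_grid(grid: BiasGrid, path: str | Path,
                    p: WTParams | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# s V_G (kJ/mol)\n")
        if p is not None:
            fh.write(f"#! SET T {p.T:.10g}\n")
            fh.write(f"#! SET deltaT {p.deltaT:.10g}\n")
        for s, v in zip(grid.nodes, grid.values):
            fh.write(f"{s:.10g} {v:.10g}\n")


# -- metastatistics ensembles -------------------------------------------------

def read_ensemble(path: str | Path, cv: str = "xi") -> Metastatistics:
    """Read a frame table (time walker xi [xi_prime] energy) as Metastatistics.

    ``cv`` selects the column the MEC constraint acts on.
    """
    df = _read_fields_table(path)
    for col in ("time", "walker", "xi", "energy"):
        if col not in df:
            raise ValueError(f"ensemble table needs a '{col}' column")
    ms = Metastatistics(
        df["xi"].to_numpy(), df["energy"].to_numpy(),
        df["multiplicity"].to_numpy() if "multiplicity" in df else None,
        df["walker"].to_numpy(dtype=int), df["time"].to_numpy(),
        df["xi_prime"].to_numpy() if "xi_prime" in df else None,
    )
    return ms.with_cv(cv)


def write_ensemble(ms: Metastatistics, path: str | Path) -> None:
    data = {
        "time": np.arange(len(ms), dtype=float) if ms.time is None else ms.time,
        "walker": ms.walker,
        "xi": ms.xi,
    }
    if ms.xi_prime is not None:
        data["xi_prime"] = ms.xi_prime
    data["energy"] = ms.energy
    if not np.all(ms.multiplicity == 1):
        data["multiplicity"] = ms.multiplicity
    _write_fields_table(path, pd.DataFrame(data))


# -- PQR / PDB ----------------------------------------------------------------

def read_pqr(path: str | Path, sigma_default: float = SIGMA_DEFAULT,
             sigma_overrides: dict[str, float] | None = None) -> SoluteModel:
    """Read PQR atom records (whitespace PDB dialect with charge and radius).

    ``sigma_overrides`` maps atom-name prefixes to per-atom SASA
    coefficients; unmatched atoms get ``sigma_default``.
    """
    coords, charges, radii, names = [], [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        # PQR: record serial name resname [chain] resnum x y z charge radius
        x, y, z, q, r = (float(v) for v in parts[-5:])
        coords.append([x, y, z])
        charges.append(q)
        radii.append(r)
        names.append(parts[2])
    if not coords:
        raise ValueError(f"{path}: no ATOM records")
    sigmas = []
    overrides = sigma_overrides or {}
    for name in names:
        sigma = sigma_default
        for pattern, value in overrides.items():
            if name.startswith(pattern):
                sigma = value
                break
        sigmas.append(sigma)
    return SoluteModel(np.array(coords), np.array(charges), np.array(radii),
                       np.array(sigmas), names)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file (via Biopython)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    current_chain = None
    current_res = None
    for a in structure.atoms:
        if a.chain != current_chain:
            builder.init_chain(a.chain)
            builder.init_seg("    ")
            current_chain = a.chain
            current_res = None
        if a.residue_number != current_res:
            builder.init_residue(a.residue_name, " ", a.residue_number, " ")
            current_res = a.residue_number
        builder.init_atom(a.atom_name, a.position.astype(np.float32), 0.0, 1.0,
                          " ", a.atom_name.ljust(3), a.atom_id,
                          element=a.atom_name[0])
    out = PDBIO()
    out.set_structure(builder.get_structure())
    out.save(str(path))


# -- schedules ----------------------------------------------------------------

def read_schedule(path: str | Path) -> Schedule:
    """Read a staging table: stage, length_ns, alpha, w_share, bias_updated.

    '-' marks stages where the bias is not updated (alpha/w absent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"stage", "length_ns", "alpha", "w_share"}
    if not required.issubset(df.columns):
        raise ValueError(f"schedule needs columns {sorted(required)}")

    def _opt(v):
        v = str(v).strip()
        if v in ("-", "", "nan", "None"):
            return None
        if "/" in v:
            num, den = v.split("/")
            return float(num) / float(den)
        return float(v)

    stages = []
    for r in df.itertuples():
        alpha = _opt(r.alpha)
        w = _opt(r.w_share)
        stages.append(Stage(str(r.stage), float(r.length_ns), alpha, w,
                            bias_updated=alpha is not None))
    return Schedule(stages)


def write_schedule(schedule: Schedule, path: str | Path) -> None:
    rows = []
    for st in schedule.stages:
        rows.append({
            "stage": st.label,
            "length_ns": st.duration_ns,
            "alpha": "-" if st.alpha is None else st.alpha,
            "w_share": "-" if st.w_share is None else st.w_share,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
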