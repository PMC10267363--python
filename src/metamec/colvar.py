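"""Hydrogen-bond collective variables.

The degree of folding of a small protein is monitored here through a
continuous count of native backbone hydrogen bonds.  Each donor--acceptor
pair (heavy atoms only: amide N to carbonyl O) contributes a value in
[0, 1] given by a rational switching function of the N--O distance, so the
collective variable xi is a smooth, differentiable proxy for the number of
intact native contacts.  Pairs are grouped by the secondary-structure
element they belong to (``beta``, ``alpha1``, ``alpha2``); the extended
variable xi' adds the helical groups on top of the beta-sheet count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "HBondPair",
    "SwitchingParams",
    "CVSeries",
    "GROUPS",
    "load_structure",
    "load_frames",
    "switching_value",
    "count_hbonds",
    "extended_cv",
    "cv_distribution",
]

GROUPS = ("beta", "alpha1", "alpha2")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity, position and (optional) electrostatic data."""

    atom_id: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray  # shape (3,), Angstrom
    charge: float | None = None  # elementary charges
    radius: float | None = None  # Angstrom

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered collection of atoms for one frame.

    Selector lookup is by ``(residue_number, atom_name)``; ambiguous
    selectors (e.g. two chains with the same residue numbering) raise on
    access, not on load.
    """

    def __init__(self, atoms: Sequence[AtomRecord], frame_time: float | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("Structure requires at least one atom")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique within a Structure")
        self.atoms = atoms
        self.frame_time = frame_time
        self._index: dict[tuple[int, str], list[int]] = {}
        for i, a in enumerate(atoms):
            self._index.setdefault((a.residue_number, a.atom_name), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def atom(self, residue_number: int, atom_name: str) -> AtomRecord:
        hits = self._index.get((residue_number, atom_name), [])
        if not hits:
            raise KeyError(f"no atom matches selector ({residue_number}, {atom_name!r})")
        if len(hits) > 1:
            raise KeyError(
                f"selector ({residue_number}, {atom_name!r}) is ambiguous: "
                f"{len(hits)} atoms match"
            )
        return self.atoms[hits[0]]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Return a rigidly moved copy (rotation applied about the origin)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = [
            AtomRecord(a.atom_id, a.atom_name, a.residue_name, a.residue_number,
                       a.chain, R @ a.position + t, a.charge, a.radius)
            for a in self.atoms
        ]
        return Structure(atoms, self.frame_time)


@dataclass(frozen=True)
class HBondPair:
    """A donor->acceptor atom pair with its secondary-structure group label.

    Selectors match by residue number and atom name only, never residue
    name, so the same pair list applies unchanged to point mutants that
    keep their backbone N/O atoms.
    """

    donor_selector: tuple[int, str]
    acceptor_selector: tuple[int, str]
    group: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.donor_selector == self.acceptor_selector:
            raise ValueError("donor and acceptor selectors must differ")


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switch (1 - x^n)/(1 - x^m), x = (r-d0)/r0.

    Defaults (r0 = 2.5 A on the N--O heavy-atom distance, d0 = 0, n = 8,
    m = 12) are the conventional continuous hydrogen-bond counter used
    with metadynamics; all four are configurable.
    """

    r0: float = 2.5
    d0: float = 0.0
    n: int = 8
    m: int = 12

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("need m > n > 0")
        if self.n % 2 or self.m % 2:
            raise ValueError("n and m must be even")


@dataclass
class CVSeries:
    """Per-frame collective-variable values along a trajectory."""

    times: np.ndarray  # ps
    xi: np.ndarray  # dimensionless H-bond count
    xi_prime: np.ndarray | None = None
    walker: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.xi = np.asarray(self.xi, float)
        if self.times.shape != self.xi.shape:
            raise ValueError("times and xi must have equal length")
        if self.xi_prime is not None:
            self.xi_prime = np.asarray(self.xi_prime, float)
            if self.xi_prime.shape != self.xi.shape:
                raise ValueError("xi_prime must align with xi")
            if np.any(self.xi_prime < self.xi - 1e-9):
                raise ValueError("xi_prime must be >= xi (it adds the helical groups)")

    def __len__(self) -> int:
        return len(self.times)


def load_structure(path: str | Path) -> Structure:
    """Read the first model of a PDB file into a Structure."""
    frames = load_frames(path)
    return frames[0]


def load_frames(path: str | Path) -> list[Structure]:
    """Read a (possibly multi-model) PDB file; each MODEL is one frame."""
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate nonstandard toy PDBs
        model_list = list(PDBParser(QUIET=True).get_structure("s", str(path)))
    frames = []
    for model in model_list:
        atoms = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atoms.append(AtomRecord(
                        atom_id=atom.serial_number,
                        atom_name=atom.get_name(),
                        residue_name=residue.get_resname(),
                        residue_number=residue.get_id()[1],
                        chain=chain.get_id(),
                        position=np.asarray(atom.get_coord(), float),
                    ))
        if atoms:
            frames.append(Structure(atoms))
    if not frames:
        raise ValueError(f"{path}: no ATOM records found")
    return frames


def switching_value(r, p: SwitchingParams = SwitchingParams()):
    """Rational switch (1 - x^n)/(1 - x^m) with x = (r - d0)/r0.

    Evaluated through the equivalent geometric-sum form
    (sum_{k<n} x^k) / (sum_{k<m} x^k), which is exact for x != 1 and
    continuously extends to n/m at x = 1.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    x = (r - p.d0) / p.r0
    # Horner evaluation of the two geometric sums.
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    for _ in range(p.n):
        num = num * x + 1.0
    for _ in range(p.m):
        den = den * x + 1.0
    out = num / den
    return float(out) if out.ndim == 0 else out


def _pair_distance(frame: Structure, pair: HBondPair) -> float:
    try:
        d = frame.atom(*pair.donor_selector)
        a = frame.atom(*pair.acceptor_selector)
    except KeyError as exc:
        raise KeyError(
            f"cannot resolve pair {pair.donor_selector} -> {pair.acceptor_selector}: {exc}"
        ) from exc
    return float(np.linalg.norm(d.position - a.position))


def count_hbonds(frame: Structure, pairs: Iterable[HBondPair],
                 p: SwitchingParams = SwitchingParams(),
                 groups: Iterable[str] | None = None) -> float:
    """Continuous hydrogen-bond count over the selected groups."""
    wanted = set(GROUPS) if groups is None else set(groups)
    unknown = wanted - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    total = 0.0
    for pair in pairs:
        if pair.group in wanted:
            total += switching_value(_pair_distance(frame, pair), p)
    return total


def extended_cv(frame: Structure, pairs: Iterable[HBondPair],
                p: SwitchingParams = SwitchingParams()) -> tuple[float, float]:
    """Return (xi, xi') = (beta-sheet count, beta + helix count).

    The extended variable augments the beta-sheet hydrogen-bond count
    biased during sampling with the helical hydrogen bonds, so that the
    subsequent entropy-constrained analysis can see helix melting that the
    bias alone does not resolve.
    """
    pairs = list(pairs)
    xi = count_hbonds(frame, pairs, p, groups={"beta"})
    alpha = count_hbonds(frame, pairs, p, groups={"alpha1", "alpha2"})
    return xi, xi + alpha


def cv_distribution(xi: np.ndarray | CVSeries, bin_edges: np.ndarray) -> np.ndarray:
    """Histogram of CV values normalised so that sum_i P_i = 1."""
    if isinstance(xi, CVSeries):
        xi = xi.xi
    xi = np.asarray(xi, float)
    if xi.size == 0:
        raise ValueError("empty CV series")
    counts, _ = np.histogram(xi, bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no CV values fall inside the requested bins")
    return counts / total
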