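"""Structure parsing, ligand-pocket identification and spatial neighborhoods.

Positions are addressed as ``(chain, residue_number)`` pairs using author
numbering.  All distance criteria operate on heavy atoms only; hydrogens are
stripped on parse and alternative conformations are resolved to the highest
occupancy.

A *neighborhood* is a designed position together with every designed position
in direct atomic contact with it — by default at least two heavy atoms of the
candidate residue within 6 A of the center residue.  Because the contact
criterion is symmetric, proximal neighborhoods overlap, which is what lets
downstream training data capture pairwise couplings between positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

Position = tuple[str, int]  # (chain id, author residue number)

#: van der Waals radii (A) for heavy elements; fallback 1.70
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: theoretical maximum accessible surface areas (A^2) per residue, used to
#: normalise raw SASA into relative burial (Tien et al. 2013 scale)
MAX_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueRecord:
    chain: str
    number: int
    name: str  # three-letter residue name
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates
    elements: tuple[str, ...]

    @property
    def position(self) -> Position:
        return (self.chain, self.number)


@dataclass(frozen=True)
class Structure:
    residues: tuple[ResidueRecord, ...]
    ligand: Position

    def __post_init__(self) -> None:
        seen = set()
        for r in self.residues:
            if r.position in seen:
                raise ValueError(f"duplicate residue {r.position}")
            seen.add(r.position)
            if not np.all(np.isfinite(r.coords)):
                raise ValueError(f"non-finite coordinates in residue {r.position}")
        if self.ligand not in seen:
            raise ValueError(f"ligand residue {self.ligand} absent from structure")

    def residue(self, position: Position) -> ResidueRecord:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"no residue at {position}")

    @property
    def positions(self) -> list[Position]:
        return [r.position for r in self.residues]


@dataclass(frozen=True)
class Neighborhood:
    """A designed center plus the designed positions in contact with it."""

    center: Position
    members: tuple[Position, ...]  # center first

    def __post_init__(self) -> None:
        if not self.members or self.members[0] != self.center:
            raise ValueError("neighborhood members must start with the center")


def parse_structure(path, ligand_name: str) -> Structure:
    """Parse a PDB file, keeping heavy atoms and highest-occupancy altlocs."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure {path}: {exc}") from exc
    st.remove_hydrogens()
    model = st[0]
    residues: list[ResidueRecord] = []
    ligand: Position | None = None
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            atoms = list(best.values())
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            elements = tuple(a.element.name.upper() for a in atoms)
            rec = ResidueRecord(chain.name, res.seqid.num, res.name, coords, elements)
            residues.append(rec)
            if res.name == ligand_name:
                ligand = rec.position
    if ligand is None:
        raise ValueError(f"ligand residue {ligand_name!r} not found in {path}")
    return Structure(tuple(residues), ligand)


def residue_contacts(
    s: Structure,
    center: Position,
    cutoff: float = 6.0,
    min_atom_pairs: int = 2,
) -> set[Position]:
    """Positions with >= ``min_atom_pairs`` heavy atoms within ``cutoff`` of the center.

    Each qualifying atom of the candidate residue must lie within ``cutoff``
    of *some* heavy atom of the center residue; the center itself is excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    center_res = s.residue(center)
    tree = cKDTree(center_res.coords)
    contacts: set[Position] = set()
    for r in s.residues:
        if r.position == center:
            continue
        dists, _ = tree.query(r.coords, k=1)
        if int(np.sum(np.atleast_1d(dists) <= cutoff)) >= min_atom_pairs:
            contacts.add(r.position)
    return contacts


def ligand_shell(s: Structure, cutoff: float = 8.0) -> set[Position]:
    """Positions with any heavy atom within ``cutoff`` of any ligand heavy atom."""
    lig = s.residue(s.ligand)
    tree = cKDTree(lig.coords)
    shell: set[Position] = set()
    for r in s.residues:
        if r.position == s.ligand:
            continue
        if cutoff <= 0:
            continue
        dists, _ = tree.query(r.coords, k=1)
        if np.min(np.atleast_1d(dists)) <= cutoff:
            shell.add(r.position)
    return shell


def build_neighborhoods(
    s: Structure,
    designed: Sequence[Position],
    cutoff: float = 6.0,
    min_atom_pairs: int = 2,
    prune: Mapping[Position, Iterable[Position]] | None = None,
) -> list[Neighborhood]:
    """One neighborhood per designed position, members restricted to designed.

    ``prune`` supplies per-center exclusion lists for contacts judged (e.g. on
    manual inspection) not to interact directly with the center.
    """
    designed_set = set(designed)
    missing = designed_set - set(s.positions)
    if missing:
        raise KeyError(f"designed positions absent from structure: {sorted(missing)}")
    prune = {k: set(v) for k, v in (prune or {}).items()}
    out = []
    for center in designed:
        excluded = prune.get(center, set())
        if center in excluded:
            raise ValueError(f"cannot prune neighborhood center {center}")
        members = residue_contacts(s, center, cutoff, min_atom_pairs)
        members = sorted((members & designed_set) - excluded)
        out.append(Neighborhood(center, (center, *members)))
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas by sphere sampling.

    Each atom's expanded sphere (radius + probe) is sampled with a fixed
    Fibonacci lattice; a sample point is accessible when it lies outside every
    other atom's expanded sphere.  Area = accessible fraction x 4*pi*R^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    max_r = expanded.max() if len(expanded) else 0.0
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def relative_sasa(
    s: Structure, probe: float = 1.4, n_points: int = 960
) -> dict[Position, float]:
    """Per-residue SASA normalised by the per-amino-acid theoretical maximum.

    The ligand residue (no tabulated maximum) is reported as raw area / NaN-free
    by normalising with the sum of isolated-atom sphere areas.
    """
    coords = np.vstack([r.coords for r in s.residues])
    radii = np.concatenate(
        [[VDW_RADII.get(e, 1.70) for e in r.elements] for r in s.residues]
    )
    areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    out: dict[Position, float] = {}
    k = 0
    for r in s.residues:
        n = len(r.coords)
        total = float(areas[k : k + n].sum())
        k += n
        one = THREE_TO_ONE.get(r.name)
        if one is not None:
            out[r.position] = total / MAX_SASA[one]
        else:
            iso = float(
                np.sum(4.0 * np.pi * (np.array(
                    [VDW_RADII.get(e, 1.70) for e in r.elements]) + probe) ** 2)
            )
            out[r.position] = total / iso
    return out


def buried_positions(
    sasa: Mapping[Position, float], threshold: float = 0.2
) -> set[Position]:
    """Positions whose relative accessibility falls below the burial cutoff."""
    return {pos for pos, rel in sasa.items() if rel < threshold}


def max_sasa_delta(ref_aa: str, mut_aa: str) -> float:
    """Difference of tabulated per-amino-acid maximum accessible areas (mut - ref)."""
    return MAX_SASA[mut_aa] - MAX_SASA[ref_aa]


def write_neighborhoods(neighborhoods: Sequence[Neighborhood], path) -> None:
    payload = [
        {"center": list(n.center), "members": [list(m) for m in n.members]}
        for n in neighborhoods
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_neighborhoods(path) -> list[Neighborhood]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Neighborhood(tuple(d["center"]), tuple(tuple(m) for m in d["members"]))
        for d in payload
    ]


def write_sasa_table(sasa: Mapping[Position, float], path) -> None:
    frame = pd.DataFrame(
        [(c, n, v) for (c, n), v in sorted(sasa.items())],
        columns=["chain", "residue", "relative_sasa"],
    )
    frame.to_csv(path, sep="\t", index=False)
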