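"""Structural validation of coupling scores against inter-residue distances.

Residues are represented by their Cβ atom (Cα for glycine, which has no
Cβ); a pair is in physical contact when its representative-atom distance is
at or below the 8 Å CASP cutoff.  The predictive-power statistic asks how
many of an algorithm's 75 top-scoring pairs fall at or below the median
distance and converts that count to a binomial tail probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

from .covariance import ScoreMatrix

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ResidueCoordinates:
    """Representative-atom coordinates per residue number, in Å."""

    coords: dict[int, np.ndarray]
    source: str = ""
    chain: str = ""
    #: optional per-residue backbone atom coordinates for RMSD
    backbone: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"residue {r}: bad coordinates {xyz}")
            self.coords[r] = xyz

    @property
    def residues(self) -> list[int]:
        return sorted(self.coords)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix over a residue set, in Å."""

    positions: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        d = np.asarray(self.distances, dtype=float)
        n = len(self.positions)
        if d.shape != (n, n):
            raise ValueError("distance matrix must be square over positions")
        self.distances = d

    def distance(self, pos_i: int, pos_j: int) -> float:
        lookup = {int(p): k for k, p in enumerate(self.positions)}
        return float(self.distances[lookup[pos_i], lookup[pos_j]])


@dataclass
class StructureComparison:
    """Join of coupling scores with structural distances, plus the
    binomial predictive-power summary."""

    algorithm: str
    table: pd.DataFrame  # pos_i, pos_j, score, distance, contact
    median_retained: float
    median_unfiltered: float
    top: int
    n_below_median: int
    p_value: float

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.table.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        prefix.with_suffix(".json").write_text(json.dumps({
            "algorithm": self.algorithm,
            "median_retained_A": self.median_retained,
            "median_unfiltered_A": self.median_unfiltered,
            "top": self.top,
            "n_below_median": self.n_below_median,
            "binomial_p_value": self.p_value,
        }, indent=2))


def read_cbeta_coordinates(
    pdb_path: str | Path,
    chain: str,
    res_range: tuple[int, int] | None = None,
) -> ResidueCoordinates:
    """Cβ coordinates (Cα for glycine) for one chain of a PDB file.

    Only the first model is read; hetero residues are skipped; residues
    absent from the model are simply omitted; altloc is resolved to the
    highest-occupancy conformer; insertion codes are rejected.
    """
    pdb_path = Path(pdb_path)
    structure = PDBParser(QUIET=True).get_structure(pdb_path.stem, str(pdb_path))
    model = next(iter(structure))
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not found in {pdb_path}")
    coords: dict[int, np.ndarray] = {}
    backbone: dict[int, dict[str, np.ndarray]] = {}
    for res in model[chain]:
        hetflag, resnum, icode = res.id
        if hetflag != " ":
            continue
        if icode != " ":
            raise ValueError(
                f"insertion code {icode!r} at residue {resnum}: not supported"
            )
        if res_range is not None and not (res_range[0] <= resnum <= res_range[1]):
            continue
        atom = None
        if "CB" in res:
            atom = res["CB"]
        elif "CA" in res:  # glycine, or a model without the side chain
            atom = res["CA"]
        if atom is None:
            continue
        coords[resnum] = np.array(atom.get_coord(), dtype=float)
        bb = {}
        for name in BACKBONE_ATOMS:
            if name in res:
                bb[name] = np.array(res[name].get_coord(), dtype=float)
        backbone[resnum] = bb
    if not coords:
        raise ValueError(f"no residues selected from {pdb_path} chain {chain} {res_range}")
    return ResidueCoordinates(coords, source=pdb_path.stem, chain=chain, backbone=backbone)


def pairwise_distances(rc: ResidueCoordinates) -> DistanceMatrix:
    """All-pairs Euclidean distances d = sqrt(dx^2 + dy^2 + dz^2)."""
    if len(rc) < 2:
        raise ValueError("need at least 2 residues for distances")
    pos = rc.residues
    xyz = np.stack([rc.coords[r] for r in pos])
    diff = xyz[:, None, :] - xyz[None, :, :]
    return DistanceMatrix(np.array(pos), np.sqrt((diff**2).sum(axis=2)))


def classify_contacts(dm: DistanceMatrix, cutoff: float = 8.0) -> dict[tuple[int, int], bool]:
    """Contact map: pair -> (distance <= cutoff), inclusive, upper triangle."""
    out: dict[tuple[int, int], bool] = {}
    n = len(dm.positions)
    for a in range(n):
        for b in range(a + 1, n):
            out[(int(dm.positions[a]), int(dm.positions[b]))] = bool(
                dm.distances[a, b] <= cutoff
            )
    return out


def binomial_pvalue(n_below: int, top: int = 75) -> float:
    """P[X >= n_below] for X ~ Binomial(top, 1/2), computed exactly.

    The probability that an algorithm choosing pairs at random would put at
    least ``n_below`` of its ``top`` pairs below the median distance.
    """
    if not (0 <= n_below <= top):
        raise ValueError(f"n_below must be in [0, {top}], got {n_below}")
    half = Fraction(1, 2) ** top
    total = sum(comb(top, k) for k in range(n_below, top + 1))
    return float(total * half)


def score_distance_table(
    sm: ScoreMatrix,
    dm: DistanceMatrix,
    min_separation: int = 8,
    min_ungapped_frac: float = 0.65,
    ungapped_frac: Mapping[int, float] | None = None,
    top: int = 75,
    contact_cutoff: float = 8.0,
) -> StructureComparison:
    """Join coupling scores with Cβ–Cβ distances and summarize power.

    Pairs separated by at most ``min_separation`` sequence positions are
    excluded (local-contact bias), as is any position whose un-gapped row
    fraction falls below ``min_ungapped_frac`` (requires ``ungapped_frac``;
    when omitted the gap filter is skipped).  The summary counts how many
    of the ``top`` highest-scoring retained pairs lie at or below the
    median retained distance, with its binomial tail probability; the
    median over all structurally resolved pairs is reported alongside.
    """
    dpos = set(int(p) for p in dm.positions)
    records = []
    all_distances = []
    n = len(dm.positions)
    for a in range(n):
        for b in range(a + 1, n):
            all_distances.append(dm.distances[a, b])
    for pi, pj, score in sm.iter_pairs():
        if pi not in dpos or pj not in dpos:
            continue
        if abs(pi - pj) <= min_separation:
            continue
        if ungapped_frac is not None and (
            ungapped_frac.get(pi, 1.0) < min_ungapped_frac
            or ungapped_frac.get(pj, 1.0) < min_ungapped_frac
        ):
            continue
        d = dm.distance(pi, pj)
        records.append((pi, pj, score, d, d <= contact_cutoff))
    if not records:
        raise ValueError("no pairs survive the join and filters")
    table = pd.DataFrame(records, columns=["pos_i", "pos_j", "score", "distance", "contact"])
    median_retained = float(table["distance"].median())
    median_unfiltered = float(np.median(all_distances))
    top_n = min(top, len(table))
    ranked = table.sort_values(
        ["score", "pos_i", "pos_j"], ascending=[False, True, True]
    ).head(top_n)
    n_below = int((ranked["distance"] <= median_retained).sum())
    p = binomial_pvalue(n_below, top_n)
    return StructureComparison(sm.algorithm, table, median_retained,
                               median_unfiltered, top_n, n_below, p)


def kabsch_rmsd(
    a: ResidueCoordinates, b: ResidueCoordinates, atoms: tuple[str, ...] = BACKBONE_ATOMS
) -> float:
    """Least-squares backbone RMSD after optimal rigid superposition.

    Uses the residues present in both structures and, per residue, the
    requested atoms present in both.
    """
    xs, ys = [], []
    common = sorted(set(a.coords) & set(b.coords))
    for r in common:
        bb_a = a.backbone.get(r, {})
        bb_b = b.backbone.get(r, {})
        for name in atoms:
            if name in bb_a and name in bb_b:
                xs.append(bb_a[name])
                ys.append(bb_b[name])
    if len(common) < 3 or len(xs) < 3:
        raise ValueError(f"need >=3 common residues with shared atoms, got {len(common)}")
    sup = SVDSuperimposer()
    sup.set(np.stack(xs), np.stack(ys))
    sup.run()
    return float(sup.get_rms())


def write_pdb(rc: ResidueCoordinates, path: str | Path, chain: str = "A") -> None:
    """Write representative atoms as a minimal single-chain PDB file.

    Each residue is emitted as one alanine CB record (toy structures only).
    """
    lines = []
    serial = 1
    for r in rc.residues:
        x, y, z = rc.coords[r]
        lines.append(
            f"ATOM  {serial:5d}  CB  ALA {chain}{r:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
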