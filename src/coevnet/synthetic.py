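"""Synthetic alignments and toy structures with known ground truth.

The generator emulates a dereplicated protein family alignment — a few
hundred to a few thousand sequences over ~250 columns with per-column
conservation, a gap process, and taxon labels — and plants covarying
column pairs of tunable strength.  Coupling is a mixture: with probability
``coupling`` a row's residue pair at a planted pair is drawn jointly from
a residue-pair table, otherwise the two columns are drawn independently
from their own profiles, which gives a closed-form expected MI at full
strength.  A planted pair may be conditioned on a "mutation" column so
that the coupling exists only in the rows carrying a given residue there,
mirroring mutation-defined perturbation analysis.

Phylogenetic correlation between rows is deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .matrices import AMINO_ACIDS, N_AA
from .structure import ResidueCoordinates

DEFAULT_TAXA = {"animal": 0.4, "fungi": 0.3, "plant": 0.15, "protist": 0.1, "bacteria": 0.05}


@dataclass(frozen=True)
class PlantedPair:
    """A covarying column pair planted into the alignment.

    ``joint`` maps residue pairs to probabilities (normalised at build).
    When ``condition_col``/``condition_residue`` are set, the joint draw
    applies only to rows carrying that residue at that column.
    """

    col_i: int
    col_j: int
    coupling: float
    joint: dict[tuple[str, str], float] | None = None
    condition_col: int | None = None
    condition_residue: str | None = None

    def __post_init__(self) -> None:
        if self.col_i == self.col_j:
            raise ValueError("planted pair columns must be distinct")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling strength must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic alignment."""

    n_seqs: int = 1000
    n_cols: int = 250
    #: top-residue probability per column (scalar or length-n_cols array);
    #: 1/20 gives uniform columns
    conservation: float | np.ndarray = 0.5
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    gap_rate: float = 0.02
    taxon_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAXA))
    seed: int = 0
    #: pin the consensus residue of selected columns (e.g. a mutation column
    #: whose major residue a conditional planted pair refers to)
    top_residue_overrides: dict[int, str] = field(default_factory=dict)

    def conservation_profile(self) -> np.ndarray:
        c = np.broadcast_to(np.asarray(self.conservation, dtype=float), (self.n_cols,))
        if np.any(c < 1.0 / N_AA - 1e-12) or np.any(c > 1.0):
            raise ValueError("conservation must lie in [1/20, 1]")
        return np.array(c)

    def validate(self) -> None:
        if self.n_seqs < 2 or self.n_cols < 2:
            raise ValueError("need at least 2 sequences and 2 columns")
        if not (0.0 <= self.gap_rate < 1.0):
            raise ValueError("gap_rate must lie in [0, 1)")
        seen = set()
        for p in self.planted_pairs:
            for c in (p.col_i, p.col_j):
                if not (0 <= c < self.n_cols):
                    raise ValueError(f"planted column {c} out of range")
                if c in seen:
                    raise ValueError(f"column {c} used by more than one planted pair")
                seen.add(c)
        self.conservation_profile()


@dataclass
class GroundTruth:
    """What was planted: spec plus realized per-column profiles."""

    spec: SyntheticSpec
    top_residue: list[str]
    planted: list[PlantedPair]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "seed": self.spec.seed,
            "n_seqs": self.spec.n_seqs,
            "n_cols": self.spec.n_cols,
            "gap_rate": self.spec.gap_rate,
            "top_residue": self.top_residue,
            "planted_pairs": [
                {
                    "col_i": p.col_i, "col_j": p.col_j, "coupling": p.coupling,
                    "condition_col": p.condition_col,
                    "condition_residue": p.condition_residue,
                }
                for p in self.planted
            ],
        }, indent=2))


def _column_profile(top_idx: int, top_prob: float) -> np.ndarray:
    p = np.full(N_AA, (1.0 - top_prob) / (N_AA - 1))
    p[top_idx] = top_prob
    return p


def _normalised_joint(pair: PlantedPair, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(pairs array (k,2) of residue indices, probability vector)."""
    if pair.joint is None:
        # default: a random residue bijection with uniform weight — strong,
        # 20-state covariation whose MI tends to ln 20 at full coupling
        perm = rng.permutation(N_AA)
        pairs = np.stack([np.arange(N_AA), perm], axis=1)
        probs = np.full(N_AA, 1.0 / N_AA)
        return pairs, probs
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    pairs = np.array([[idx[a], idx[b]] for a, b in pair.joint], dtype=int)
    probs = np.array(list(pair.joint.values()), dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("joint table probabilities must be non-negative and not all zero")
    return pairs, probs / probs.sum()


def generate_coupled_msa(spec: SyntheticSpec) -> tuple[Alignment, GroundTruth]:
    """Draw an alignment from the spec; deterministic under the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cons = spec.conservation_profile()
    top_idx = rng.integers(0, N_AA, size=spec.n_cols)
    for col, aa in spec.top_residue_overrides.items():
        top_idx[col] = AMINO_ACIDS.index(aa)

    # independent background draw for every cell
    enc = np.empty((spec.n_seqs, spec.n_cols), dtype=np.int64)
    for j in range(spec.n_cols):
        profile = _column_profile(int(top_idx[j]), float(cons[j]))
        enc[:, j] = rng.choice(N_AA, size=spec.n_seqs, p=profile)

    # overwrite planted pairs with the mixture draw
    for pair in spec.planted_pairs:
        pairs, probs = _normalised_joint(pair, rng)
        if pair.condition_col is not None:
            cond_idx = AMINO_ACIDS.index(pair.condition_residue)
            eligible = enc[:, pair.condition_col] == cond_idx
        else:
            eligible = np.ones(spec.n_seqs, dtype=bool)
        coupled = eligible & (rng.random(spec.n_seqs) < pair.coupling)
        k = int(coupled.sum())
        if k:
            draw = rng.choice(len(probs), size=k, p=probs)
            enc[coupled, pair.col_i] = pairs[draw, 0]
            enc[coupled, pair.col_j] = pairs[draw, 1]

    rows_chars = np.array(list(AMINO_ACIDS))[enc]
    if spec.gap_rate > 0:
        gaps = rng.random((spec.n_seqs, spec.n_cols)) < spec.gap_rate
        rows_chars[gaps] = "-"
    rows = ["".join(r) for r in rows_chars]
    seq_ids = [f"seq{i:05d}" for i in range(spec.n_seqs)]

    taxa = None
    if spec.taxon_weights:
        names = sorted(spec.taxon_weights)
        w = np.array([spec.taxon_weights[t] for t in names], dtype=float)
        w /= w.sum()
        taxa = [names[k] for k in rng.choice(len(names), size=spec.n_seqs, p=w)]

    aln = Alignment(seq_ids, rows, taxa)
    truth = GroundTruth(spec, [AMINO_ACIDS[int(t)] for t in top_idx],
                        list(spec.planted_pairs))
    return aln, truth


def generate_toy_coordinates(
    n_residues: int,
    contact_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
    contact_dist: tuple[float, float] = (4.0, 8.0),
    min_separation: float = 12.0,
    max_attempts: int = 5000,
) -> ResidueCoordinates:
    """Random 3D coordinates with requested contacts and nothing else close.

    Residues are numbered 1..n; listed pairs end up <= 8 Å apart, all other
    pairs >= 12 Å apart (rejection sampling; raises if the constraint set
    cannot be satisfied within ``max_attempts``).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    contact_pairs = [tuple(sorted(p)) for p in (contact_pairs or [])]
    contact_set = set(contact_pairs)
    for a, b in contact_set:
        if not (1 <= a <= n_residues and 1 <= b <= n_residues) or a == b:
            raise ValueError(f"bad contact pair ({a}, {b})")
    rng = np.random.default_rng(seed)
    box = min_separation * max(3.0, n_residues ** (1.0 / 3.0) * 2.0)
    partners = {}
    for a, b in contact_pairs:
        partners.setdefault(b, a)

    for _ in range(max_attempts):
        xyz = rng.uniform(0, box, size=(n_residues, 3))
        # snap each contact's second member next to its first
        for b, a in partners.items():
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r = rng.uniform(*contact_dist)
            xyz[b - 1] = xyz[a - 1] + direction * r
        d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2))
        ok = True
        for i in range(n_residues):
            for j in range(i + 1, n_residues):
                pair = (i + 1, j + 1)
                if pair in contact_set:
                    if d[i, j] > contact_dist[1]:
                        ok = False
                elif d[i, j] < min_separation:
                    ok = False
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return ResidueCoordinates(
                {i + 1: xyz[i] for i in range(n_residues)}, source="synthetic"
            )
    raise RuntimeError(
        f"could not satisfy contact constraints within {max_attempts} attempts"
    )
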