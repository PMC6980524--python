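"""Pairwise column coupling scores: OMES, McBASC, SCA, ELSC, MI, and RE.

Each algorithm consumes an :class:`~coevnet.alignment.Alignment` and returns
a symmetric :class:`ScoreMatrix` over the alignment's columns.  Frequency
computations for a pair of columns use only rows un-gapped at both columns
("valid rows") unless an algorithm states otherwise; ``X`` counts as a gap.

Score semantics
---------------
* OMES: chi-square-like sum of (observed - expected)^2 / N over residue
  pairs actually observed at a column pair.
* McBASC: |Pearson correlation| of McLachlan similarity patterns between
  two columns' N x N sequence-pair arrays; fully conserved or degenerate
  columns get the sentinel 2, remapped to 0.
* SCA: perturbation-based squared log-ratio change of column frequencies
  between the full alignment and a most-frequent-residue sub-alignment.
* ELSC: negative log ratio of subset-composition likelihoods against a
  proportionally rounded model composition.
* MI / RE: mutual information between column pairs and Kullback-Leibler
  conservation of single columns, both in nats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import gammaln

from .alignment import Alignment, ReferenceMap
from .matrices import (
    AMINO_ACIDS,
    BackgroundFrequencies,
    GAP_CODE,
    N_AA,
    N_STATES,
    SubstitutionMatrix,
)


@dataclass
class ScoreMatrix:
    """Symmetric pairwise coupling scores for one algorithm.

    ``positions`` are residue numbers (from a ReferenceMap when available,
    otherwise 0-based column indices); the diagonal is undefined and stored
    as 0; ``valid`` flags columns the algorithm considered.
    """

    algorithm: str
    positions: np.ndarray
    scores: np.ndarray
    valid: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.positions)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over positions")
        if self.valid.shape != (n,):
            raise ValueError("valid must be per-position")

    @property
    def n(self) -> int:
        return len(self.positions)

    def iter_pairs(self):
        """Yield (pos_i, pos_j, score) over the valid upper triangle."""
        for a in range(self.n):
            if not self.valid[a]:
                continue
            for b in range(a + 1, self.n):
                if self.valid[b]:
                    yield int(self.positions[a]), int(self.positions[b]), float(self.scores[a, b])

    def pair_values(self) -> np.ndarray:
        """Valid upper-triangle scores as a flat array."""
        idx = np.flatnonzero(self.valid)
        sub = self.scores[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return sub[iu]

    def score_at(self, pos_i: int, pos_j: int) -> float:
        lookup = {int(p): k for k, p in enumerate(self.positions)}
        return float(self.scores[lookup[pos_i], lookup[pos_j]])

    def copy_with(self, scores: np.ndarray, **params) -> "ScoreMatrix":
        return ScoreMatrix(self.algorithm, self.positions.copy(), scores,
                           self.valid.copy(), {**self.params, **params})

    # -- serialization -----------------------------------------------------

    def write_tsv(self, path: str | Path, long_form: bool = True) -> None:
        path = Path(path)
        if long_form:
            lines = ["pos_i\tpos_j\tscore\tvalid"]
            for a in range(self.n):
                for b in range(a + 1, self.n):
                    ok = int(self.valid[a] and self.valid[b])
                    lines.append(
                        f"{self.positions[a]}\t{self.positions[b]}\t{self.scores[a, b]:.10g}\t{ok}"
                    )
            path.write_text("\n".join(lines) + "\n")
        else:
            header = "\t".join(["pos"] + [str(p) for p in self.positions])
            lines = [header]
            for a in range(self.n):
                vals = "\t".join(f"{v:.10g}" for v in self.scores[a])
                lines.append(f"{self.positions[a]}\t{vals}")
            path.write_text("\n".join(lines) + "\n")
        sidecar = {"algorithm": self.algorithm, "params": self.params,
                   "n_positions": self.n}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _positions(aln: Alignment, rmap: ReferenceMap | None) -> np.ndarray:
    if rmap is not None:
        return rmap.positions
    return np.arange(aln.n_cols)


def _pair_joint_counts(enc: np.ndarray, i: int, j: int) -> tuple[np.ndarray, int]:
    """(20x20 joint residue counts over valid rows, n_valid) for columns i, j."""
    ci, cj = enc[:, i], enc[:, j]
    ok = (ci < GAP_CODE) & (cj < GAP_CODE)
    ci, cj = ci[ok], cj[ok]
    joint = np.bincount(ci.astype(np.int64) * N_AA + cj, minlength=N_AA * N_AA)
    return joint.reshape(N_AA, N_AA).astype(float), int(ok.sum())


def omes(aln: Alignment, rmap: ReferenceMap | None = None) -> ScoreMatrix:
    """Observed-minus-expected-squared coupling.

    For each column pair, residue pairs observed at least once contribute
    (N_obs - N_ex)^2 / N_valid with N_ex from the product of single-column
    frequencies over the valid rows.  Pairs with fewer than 2 valid rows
    score 0.
    """
    enc = aln.encoded
    n = aln.n_cols
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint, nv = _pair_joint_counts(enc, i, j)
            if nv < 2:
                continue
            pi = joint.sum(axis=1) / nv
            pj = joint.sum(axis=0) / nv
            expected = np.outer(pi, pj) * nv
            obs = joint > 0
            s = float((((joint - expected) ** 2)[obs] / nv).sum())
            scores[i, j] = scores[j, i] = s
    return ScoreMatrix("omes", _positions(aln, rmap), scores, np.ones(n, bool))


def mcbasc(
    aln: Alignment,
    sub: SubstitutionMatrix | None = None,
    rmap: ReferenceMap | None = None,
) -> ScoreMatrix:
    """McLachlan-based substitution correlation.

    For column i the N x N array S_i[k, l] holds the similarity of the
    residues of sequences k and l at i (0 when either is gapped).  The score
    is |corr(S_i, S_j)| over all N^2 entries, diagonal included; zero-variance
    columns yield the sentinel 2, remapped to 0.
    """
    if sub is None:
        sub = SubstitutionMatrix.mclachlan()
    M = sub.scores  # N_STATES x N_STATES, gap row/col zero
    M2 = M * M
    enc = aln.encoded
    n_seq, n = enc.shape
    N2 = float(n_seq) ** 2
    # per-column state counts
    counts = np.stack([np.bincount(enc[:, j], minlength=N_STATES) for j in range(n)]).astype(float)
    mean = np.einsum("jx,xy,jy->j", counts, M, counts) / N2
    second = np.einsum("jx,xy,jy->j", counts, M2, counts) / N2
    var = second - mean**2
    sigma = np.sqrt(np.maximum(var, 0.0))
    degenerate = sigma <= 1e-12

    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if degenerate[i] or degenerate[j]:
                r = 2.0  # sentinel: conserved or gapped column
            else:
                C = np.bincount(
                    enc[:, i].astype(np.int64) * N_STATES + enc[:, j],
                    minlength=N_STATES * N_STATES,
                ).reshape(N_STATES, N_STATES).astype(float)
                cross = float(np.sum(C * (M @ C @ M.T))) / N2
                r = (cross - mean[i] * mean[j]) / (sigma[i] * sigma[j])
            if r == 2.0:
                s = 0.0
            else:
                s = abs(r)
            scores[i, j] = scores[j, i] = s
    return ScoreMatrix("mcbasc", _positions(aln, rmap), scores, np.ones(n, bool),
                       {"substitution_matrix": sub.name})


def _column_freqs(enc: np.ndarray, pseudo: float) -> np.ndarray:
    """(n_cols x 20) residue frequencies over un-gapped rows, floored at pseudo."""
    n_cols = enc.shape[1]
    out = np.empty((n_cols, N_AA))
    for j in range(n_cols):
        col = enc[:, j]
        col = col[col < GAP_CODE]
        c = np.bincount(col, minlength=N_AA).astype(float)
        tot = c.sum()
        f = c / tot if tot > 0 else c
        out[j] = np.where(f > 0, f, pseudo)
    return out


def sca(
    aln: Alignment,
    max_gap_frac: float = 0.2,
    min_subset: int = 5,
    pseudofreq: float | None = None,
    rmap: ReferenceMap | None = None,
) -> ScoreMatrix:
    """Statistical coupling analysis (perturbation form).

    The perturbation at column j restricts the alignment to rows carrying
    j's most frequent residue; the score is the summed squared change of the
    log frequency ratios at column i between the full alignment and that
    sub-alignment.  Columns with gap frequency > ``max_gap_frac`` are
    invalid; sub-alignments smaller than ``min_subset`` flag their pairs
    invalid (scored 0).  Zero frequencies are floored at ``pseudofreq``
    (default 1/(2 * rows of the relevant alignment)); the matrix is
    symmetrized by averaging the two directions.
    """
    enc = aln.encoded
    n = aln.n_cols
    valid = aln.gap_fraction() <= max_gap_frac

    def stats(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eps = pseudofreq if pseudofreq is not None else 1.0 / (2.0 * e.shape[0])
        freqs = _column_freqs(e, eps)
        flat = e[e < GAP_CODE]
        msa = np.bincount(flat, minlength=N_AA).astype(float)
        msa /= msa.sum()
        msa = np.where(msa > 0, msa, eps)
        return freqs, msa

    full_f, full_msa = stats(enc)
    base = np.log(full_f / full_msa[None, :])  # (n, 20)

    directed = np.zeros((n, n))
    pair_ok = np.ones((n, n), bool)
    for j in range(n):
        if not valid[j]:
            continue
        col = enc[:, j]
        res = col[col < GAP_CODE]
        if res.size == 0:
            pair_ok[:, j] = pair_ok[j, :] = False
            continue
        top = int(np.bincount(res, minlength=N_AA).argmax())
        rows = np.flatnonzero(col == top)
        if rows.size < min_subset:
            pair_ok[:, j] = pair_ok[j, :] = False
            continue
        sub_f, sub_msa = stats(enc[rows])
        pert = np.log(sub_f / sub_msa[None, :])
        directed[:, j] = ((pert - base) ** 2).sum(axis=1)
    scores = (directed + directed.T) / 2.0
    scores[~pair_ok] = 0.0
    scores[~valid, :] = 0.0
    scores[:, ~valid] = 0.0
    np.fill_diagonal(scores, 0.0)
    return ScoreMatrix("sca", _positions(aln, rmap), scores, valid,
                       {"max_gap_frac": max_gap_frac, "min_subset": min_subset})


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the exact quotas and hands remaining units to the largest
    fractional remainders (ties to the lower index, deterministic).
    """
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights * (total / weights.sum())
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short > 0:
        rem = quota - base
        order = np.lexsort((np.arange(len(weights)), -rem))
        base[order[:short]] += 1
    return base


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def elsc(aln: Alignment, rmap: ReferenceMap | None = None) -> ScoreMatrix:
    """Explicit likelihood of subset covariance.

    The perturbation at column i keeps the rows with i's most frequent
    residue (C_sub).  For each other column j, the observed subset
    composition n_(r,j) is compared against a model composition m_(r,j)
    proportional to the full-column composition (largest-remainder
    rounding): score(i->j) = -ln prod_r C(N_rj, n_rj) / C(N_rj, m_rj).
    Rows gapped at j are excluded from all counts; the matrix is
    symmetrized by averaging the two directions.
    """
    enc = aln.encoded
    n = aln.n_cols
    # full-MSA per-column residue counts (over rows un-gapped at that column)
    N_counts = np.stack(
        [np.bincount(enc[:, j], minlength=N_STATES)[:N_AA] for j in range(n)]
    ).astype(float)

    directed = np.zeros((n, n))
    for i in range(n):
        col = enc[:, i]
        res = col[col < GAP_CODE]
        if res.size == 0:
            continue
        top = int(np.bincount(res, minlength=N_AA).argmax())
        rows = np.flatnonzero(col == top)
        sub = enc[rows]
        n_counts = np.stack(
            [np.bincount(sub[:, j], minlength=N_STATES)[:N_AA] for j in range(n)]
        ).astype(float)
        for j in range(n):
            if j == i:
                continue
            N_r = N_counts[j]
            n_r = n_counts[j]
            n_total = int(n_r.sum())
            if n_total == 0:
                continue
            m_r = largest_remainder(N_r, n_total)
            s = float(
                (_log_choose(N_r, m_r) - _log_choose(N_r, n_r)).sum()
            )
            # largest-remainder m is not always the exact hypergeometric
            # mode; truncate the resulting hair-negative scores
            directed[i, j] = max(s, 0.0)
    scores = (directed + directed.T) / 2.0
    np.fill_diagonal(scores, 0.0)
    return ScoreMatrix("elsc", _positions(aln, rmap), scores, np.ones(n, bool))


def mutual_information(aln: Alignment, rmap: ReferenceMap | None = None) -> ScoreMatrix:
    """MI(i,j) = sum p(x,y) ln[p(x,y)/(p(x)p(y))] in nats over valid rows."""
    enc = aln.encoded
    n = aln.n_cols
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint, nv = _pair_joint_counts(enc, i, j)
            if nv < 2:
                continue
            p = joint / nv
            pi = p.sum(axis=1)
            pj = p.sum(axis=0)
            mask = p > 0
            mi = float(np.sum(p[mask] * np.log(p[mask] / np.outer(pi, pj)[mask])))
            scores[i, j] = scores[j, i] = max(mi, 0.0)
    return ScoreMatrix("mi", _positions(aln, rmap), scores, np.ones(n, bool))


@dataclass
class ColumnScores:
    """Per-position scores (e.g. relative entropy) with a validity mask."""

    algorithm: str
    positions: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def value_at(self, pos: int) -> float:
        lookup = {int(p): k for k, p in enumerate(self.positions)}
        return float(self.values[lookup[pos]])


def relative_entropy(
    aln: Alignment,
    bg: BackgroundFrequencies | None = None,
    rmap: ReferenceMap | None = None,
) -> ColumnScores:
    """RE(i) = sum_x p(x_i) ln[p(x_i)/q(x)] in nats; gaps excluded.

    Columns with no residues at all are flagged invalid.
    """
    if bg is None:
        bg = BackgroundFrequencies.yeast()
    enc = aln.encoded
    n = aln.n_cols
    values = np.zeros(n)
    valid = np.ones(n, bool)
    for j in range(n):
        col = enc[:, j]
        col = col[col < GAP_CODE]
        if col.size == 0:
            valid[j] = False
            continue
        p = np.bincount(col, minlength=N_AA).astype(float)
        p /= p.sum()
        mask = p > 0
        values[j] = float(np.sum(p[mask] * np.log(p[mask] / bg.freqs[mask])))
    return ColumnScores("re", _positions(aln, rmap), values, valid)


def column_entropy(aln: Alignment) -> np.ndarray:
    """Shannon entropy per column in nats (gaps excluded); for MI bounds."""
    enc = aln.encoded
    out = np.zeros(aln.n_cols)
    for j in range(aln.n_cols):
        col = enc[:, j]
        col = col[col < GAP_CODE]
        if col.size == 0:
            continue
        p = np.bincount(col, minlength=N_AA).astype(float)
        p /= p.sum()
        p = p[p > 0]
        out[j] = float(-(p * np.log(p)).sum())
    return out


#: Registry of pairwise coupling algorithms by name.
ALGORITHMS: dict[str, Callable[..., ScoreMatrix]] = {
    "omes": omes,
    "mcbasc": mcbasc,
    "sca": sca,
    "elsc": elsc,
    "mi": mutual_information,
}


def compute(algorithm: str, aln: Alignment, **kwargs) -> ScoreMatrix:
    """Run a registered pairwise algorithm by name."""
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; available: {sorted(ALGORITHMS)}"
        ) from None
    return fn(aln, **kwargs)
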