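"""Scrambled-column and taxon-stratified null models, and z-scoring.

Scrambling permutes each column independently across rows: per-column
composition (consensus, conservation, RE) is preserved exactly while every
inter-column coupling is destroyed, which makes the scrambled alignment the
evolutionary-noise baseline.  The baseline cutoff is the mean over
replicates of each replicate's maximum pair score; observed scores at or
below the cutoff are zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .covariance import ALGORITHMS, ScoreMatrix, compute, largest_remainder


@dataclass
class NoiseBaseline:
    """Scrambled-alignment noise level for one algorithm."""

    algorithm: str
    replicate_maxima: list[float]
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_maxima)

    @property
    def cutoff(self) -> float:
        """Mean of the per-replicate maximum pair scores."""
        return float(np.mean(self.replicate_maxima))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "algorithm": self.algorithm,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "replicate_maxima": self.replicate_maxima,
            "cutoff": self.cutoff,
        }, indent=2))


def scramble_columns(aln: Alignment, seed: int) -> Alignment:
    """Independently permute each column's characters across rows."""
    rng = np.random.default_rng(seed)
    chars = np.array([list(row) for row in aln.rows])
    for j in range(aln.n_cols):
        chars[:, j] = chars[rng.permutation(aln.n_seqs), j]
    rows = ["".join(r) for r in chars]
    return Alignment(list(aln.seq_ids), rows,
                     list(aln.taxon) if aln.taxon is not None else None)


def scrambled_baseline(
    aln: Alignment, algorithm: str, n_replicates: int = 10, seed: int = 0, **kwargs
) -> NoiseBaseline:
    """Run ``algorithm`` on scrambled replicates; cutoff = mean of maxima."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; available: {sorted(ALGORITHMS)}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    maxima = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sm = compute(algorithm, scramble_columns(aln, rep_seed), **kwargs)
        vals = sm.pair_values()
        maxima.append(float(vals.max()) if vals.size else 0.0)
    return NoiseBaseline(algorithm, maxima, seed)


def apply_baseline(sm: ScoreMatrix, nb: NoiseBaseline) -> ScoreMatrix:
    """Zero scores at or below the scrambled cutoff (inclusive)."""
    if sm.algorithm != nb.algorithm:
        raise ValueError(
            f"algorithm mismatch: scores are {sm.algorithm!r}, baseline is {nb.algorithm!r}"
        )
    out = sm.scores.copy()
    out[out <= nb.cutoff] = 0.0
    np.fill_diagonal(out, 0.0)
    return sm.copy_with(out, baseline_cutoff=nb.cutoff)


def stratified_subsample(aln: Alignment, n: int, seed: int) -> Alignment:
    """Random subsample of ``n`` rows preserving the taxon ratio.

    Per-taxon counts are apportioned by largest remainder so they sum to
    exactly ``n``; sampling is without replacement.
    """
    if aln.taxon is None:
        raise ValueError("stratified subsampling requires taxon labels")
    if n > aln.n_seqs:
        raise ValueError(f"cannot sample {n} of {aln.n_seqs} sequences")
    taxa = sorted(set(aln.taxon))
    groups = {t: [i for i, lab in enumerate(aln.taxon) if lab == t] for t in taxa}
    counts = largest_remainder(np.array([len(groups[t]) for t in taxa]), n)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for t, k in zip(taxa, counts):
        k = min(int(k), len(groups[t]))
        chosen.extend(rng.choice(groups[t], size=k, replace=False).tolist())
    return aln.take_rows(sorted(chosen))


def pairwise_zscores(sm: ScoreMatrix) -> ScoreMatrix:
    """Convert pair scores to z-scores over the valid upper triangle.

    Uses the population (1/n) standard deviation; the transformed valid
    pairs have mean 0 and population sigma 1 by construction.
    """
    vals = sm.pair_values()
    if vals.size < 2:
        raise ValueError("need at least 2 valid pair scores for z-scoring")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    if sigma == 0:
        raise ValueError("zero variance: z-scores undefined")
    out = (sm.scores - mu) / sigma
    np.fill_diagonal(out, 0.0)
    out[~sm.valid, :] = 0.0
    out[:, ~sm.valid] = 0.0
    return sm.copy_with(out, zscored=True, z_mean=mu, z_sigma=sigma)
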