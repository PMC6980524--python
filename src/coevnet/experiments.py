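"""Reproducible study-scale experiments over synthetic alignments.

These are the package's benchmark computations: planted-pair recovery power
of the coupling algorithms, destruction of couplings by column scrambling,
perturbation-specific coupling recovery, and the dependence of top-pair
network overlap on alignment size.  Each function seeds every source of
randomness from its ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import network
from .covariance import compute
from .null_models import scramble_columns, stratified_subsample
from .synthetic import PlantedPair, SyntheticSpec, generate_coupled_msa

#: study conditions for the power experiment: a 500-sequence, 60-column
#: uniform-background alignment with one planted pair at coupling 0.9
POWER_SPEC = dict(n_seqs=500, n_cols=60, conservation=0.05, gap_rate=0.02)
POWER_PAIR = (10, 40)
POWER_COUPLING = 0.9


def pair_rank(sm, i: int, j: int) -> int:
    """1-based rank of pair (i, j) among all valid pairs, best score first."""
    pairs = sorted(sm.iter_pairs(), key=lambda t: (-t[2], t[0], t[1]))
    target = (min(i, j), max(i, j))
    for r, (a, b, _) in enumerate(pairs, 1):
        if (a, b) == target:
            return r
    raise KeyError(f"pair {target} not in score matrix")


def planted_pair_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    algorithms: tuple[str, ...] = ("mi", "omes", "elsc"),
    top_k: int = 5,
) -> dict:
    """Fraction of seeds for which each algorithm ranks the planted pair
    in its top ``top_k`` pairs, plus the pair's rank after scrambling."""
    rng = np.random.default_rng(seed)
    hits = {alg: 0 for alg in algorithms}
    scrambled_ranks = []
    i, j = POWER_PAIR
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        spec = SyntheticSpec(
            **POWER_SPEC, seed=s,
            planted_pairs=[PlantedPair(i, j, POWER_COUPLING)],
        )
        aln, _ = generate_coupled_msa(spec)
        for alg in algorithms:
            if pair_rank(compute(alg, aln), i, j) <= top_k:
                hits[alg] += 1
        scrambled = scramble_columns(aln, int(rng.integers(0, 2**31 - 1)))
        scrambled_ranks.append(pair_rank(compute("mi", scrambled), i, j))
    return {
        "n_seeds": n_seeds,
        "hits": hits,
        "recovery_pct": {alg: 100.0 * h / n_seeds for alg, h in hits.items()},
        "scrambled_median_rank": float(np.median(scrambled_ranks)),
    }


def perturbation_specificity(
    n_seeds: int = 20,
    seed: int = 0,
    top_k: int = 5,
) -> dict:
    """Recovery of a sub-population-specific coupling.

    A pair is coupled only in the rows carrying the consensus residue of a
    designated mutation column; the matching sub-alignment should rank it
    in the top ``top_k`` pairs while the complementary sub-alignment (rows
    carrying the most common alternative residue) should not.
    """
    rng = np.random.default_rng(seed)
    mut_col, (i, j) = 5, POWER_PAIR
    matching_hits = complement_hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        spec = SyntheticSpec(
            n_seqs=1000, n_cols=60, conservation=0.05, gap_rate=0.02, seed=s,
            top_residue_overrides={mut_col: "S"},
            planted_pairs=[PlantedPair(i, j, POWER_COUPLING,
                                       condition_col=mut_col,
                                       condition_residue="S")],
        )
        # give the mutation column a clear majority residue
        cons = np.full(60, 0.05)
        cons[mut_col] = 0.5
        spec.conservation = cons
        aln, _ = generate_coupled_msa(spec)
        col = aln.column(mut_col)
        matching = aln.take_rows([k for k, c in enumerate(col) if c == "S"])
        alt = max((c for c in set(col) if c not in "-XS"), key=col.count)
        complement = aln.take_rows([k for k, c in enumerate(col) if c == alt])
        if pair_rank(compute("mi", matching), i, j) <= top_k:
            matching_hits += 1
        if pair_rank(compute("mi", complement), i, j) <= top_k:
            complement_hits += 1
    return {
        "n_seeds": n_seeds,
        "matching_recovery_pct": 100.0 * matching_hits / n_seeds,
        "complement_recovery_pct": 100.0 * complement_hits / n_seeds,
    }


def subsample_overlap_trend(
    seed: int = 0,
    full_size: int = 4000,
    subset_sizes: tuple[int, ...] = (2000, 1000, 500),
    n_replicates: int = 3,
    algorithm: str = "elsc",
    top_n: int = 200,
) -> dict:
    """Mean top-N edge overlap between the full-alignment network and
    taxon-stratified subsample networks of decreasing size."""
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(
        n_seqs=full_size, n_cols=60, conservation=0.5, gap_rate=0.02,
        seed=int(rng.integers(0, 2**31 - 1)),
        planted_pairs=[
            PlantedPair(3, 33, 0.9), PlantedPair(8, 45, 0.7),
            PlantedPair(14, 52, 0.5), PlantedPair(20, 57, 0.4),
            PlantedPair(26, 48, 0.3),
        ],
    )
    full, _ = generate_coupled_msa(spec)
    full_net = network.top_pairs(compute(algorithm, full), top_n)
    means = {}
    for size in subset_sizes:
        overlaps = []
        for _ in range(n_replicates):
            sub = stratified_subsample(full, size, int(rng.integers(0, 2**31 - 1)))
            sub_net = network.top_pairs(compute(algorithm, sub), top_n)
            overlaps.append(network.edge_overlap_count(full_net, sub_net))
        means[size] = float(np.mean(overlaps))
    return {
        "full_size": full_size,
        "mean_overlap": means,
        "monotone_decreasing": all(
            means[a] > means[b] for a, b in zip(subset_sizes, subset_sizes[1:])
        ),
    }


def gaussian_tail_probability(z: float = 4.0) -> float:
    """Upper-tail probability of a standard normal at ``z``."""
    return float(norm.sf(z))


def top_fraction_pct(top_n: int = 200, n_pairs: int = 26797) -> float:
    """Percentage of ranked pairs captured by a top-N selection."""
    return 100.0 * top_n / n_pairs
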