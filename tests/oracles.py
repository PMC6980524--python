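"""Independent brute-force oracles for every coupling statistic.

These transcribe the defining formulas as literally as possible — pure
Python loops and dictionaries over character columns, no numpy encoding,
no shared code with the implementation — so they can serve as an
independent check on small alignments.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

from coevnet.matrices import AMINO_ACIDS

GAPPISH = {"-", "X"}


def _cols(aln) -> list[str]:
    return [aln.column(j) for j in range(aln.n_cols)]


def oracle_omes(aln) -> dict[tuple[int, int], float]:
    out = {}
    cols = _cols(aln)
    for i, j in combinations(range(len(cols)), 2):
        pairs = [
            (a, b)
            for a, b in zip(cols[i], cols[j])
            if a not in GAPPISH and b not in GAPPISH
        ]
        n_valid = len(pairs)
        if n_valid < 2:
            out[(i, j)] = 0.0
            continue
        counts = Counter(pairs)
        ci = Counter(a for a, _ in pairs)
        cj = Counter(b for _, b in pairs)
        total = 0.0
        for (a, b), n_obs in counts.items():
            n_ex = (ci[a] / n_valid) * (cj[b] / n_valid) * n_valid
            total += (n_obs - n_ex) ** 2 / n_valid
        out[(i, j)] = total
    return out


def oracle_mcbasc(aln, sub) -> dict[tuple[int, int], float]:
    cols = _cols(aln)
    n_seq = aln.n_seqs

    def array(col: str) -> list[list[float]]:
        return [
            [
                0.0 if col[k] in GAPPISH or col[l] in GAPPISH else sub[(col[k], col[l])]
                for l in range(n_seq)
            ]
            for k in range(n_seq)
        ]

    arrays = [array(c) for c in cols]
    means = [sum(sum(row) for row in a) / n_seq**2 for a in arrays]
    sigmas = []
    for a, m in zip(arrays, means):
        var = sum((v - m) ** 2 for row in a for v in row) / n_seq**2
        sigmas.append(math.sqrt(var))

    out = {}
    for i, j in combinations(range(len(cols)), 2):
        if sigmas[i] <= 1e-12 or sigmas[j] <= 1e-12:
            out[(i, j)] = 0.0  # sentinel 2 remapped to 0
            continue
        s = 0.0
        for k in range(n_seq):
            for l in range(n_seq):
                s += (arrays[i][k][l] - means[i]) * (arrays[j][k][l] - means[j])
        r = s / (n_seq**2 * sigmas[i] * sigmas[j])
        out[(i, j)] = abs(r)
    return out


def _freqs(col: str) -> dict[str, float]:
    residues = [c for c in col if c not in GAPPISH]
    n = len(residues)
    return {a: residues.count(a) / n for a in AMINO_ACIDS} if n else {a: 0.0 for a in AMINO_ACIDS}


def oracle_sca(aln, max_gap_frac=0.2, min_subset=1) -> dict[tuple[int, int], float]:
    cols = _cols(aln)
    n = len(cols)
    valid = [sum(c in GAPPISH for c in col) / len(col) <= max_gap_frac for col in cols]

    def msa_freqs(columns: list[str]) -> dict[str, float]:
        residues = [c for col in columns for c in col if c not in GAPPISH]
        return {a: residues.count(a) / len(residues) for a in AMINO_ACIDS}

    def floored(f: dict[str, float], eps: float) -> dict[str, float]:
        return {a: (v if v > 0 else eps) for a, v in f.items()}

    eps_full = 1.0 / (2 * aln.n_seqs)
    full_msa = floored(msa_freqs(cols), eps_full)
    full_col = [floored(_freqs(c), eps_full) for c in cols]

    directed = {}
    pair_ok = {}
    for j in range(n):
        residues = [c for c in cols[j] if c not in GAPPISH]
        if not valid[j] or not residues:
            continue
        counts = Counter(residues)
        top = min(counts, key=lambda a: (-counts[a], AMINO_ACIDS.index(a)))
        rows = [k for k, c in enumerate(cols[j]) if c == top]
        if len(rows) < min_subset:
            continue
        sub_cols = ["".join(col[k] for k in rows) for col in cols]
        eps_sub = 1.0 / (2 * len(rows))
        sub_msa = floored(msa_freqs(sub_cols), eps_sub)
        for i in range(n):
            total = 0.0
            sub_f = floored(_freqs(sub_cols[i]), eps_sub)
            for a in AMINO_ACIDS:
                term = math.log(sub_f[a] / sub_msa[a]) - math.log(
                    full_col[i][a] / full_msa[a]
                )
                total += term**2
            directed[(i, j)] = total
            pair_ok[(i, j)] = True

    out = {}
    for i, j in combinations(range(n), 2):
        if not (valid[i] and valid[j]):
            out[(i, j)] = 0.0
        elif (i, j) in directed and (j, i) in directed:
            out[(i, j)] = (directed[(i, j)] + directed[(j, i)]) / 2
        else:
            out[(i, j)] = 0.0
    return out


def _largest_remainder(weights: list[float], total: int) -> list[int]:
    if total == 0 or sum(weights) == 0:
        return [0] * len(weights)
    quotas = [w * total / sum(weights) for w in weights]
    base = [math.floor(q) for q in quotas]
    short = total - sum(base)
    order = sorted(range(len(weights)), key=lambda k: (-(quotas[k] - base[k]), k))
    for k in order[:short]:
        base[k] += 1
    return base


def oracle_elsc(aln) -> dict[tuple[int, int], float]:
    cols = _cols(aln)
    n = len(cols)

    def directed(i: int, j: int) -> float:
        residues = [c for c in cols[i] if c not in GAPPISH]
        if not residues:
            return 0.0
        counts = Counter(residues)
        top = min(counts, key=lambda a: (-counts[a], AMINO_ACIDS.index(a)))
        rows = [k for k, c in enumerate(cols[i]) if c == top]
        N = Counter(c for c in cols[j] if c not in GAPPISH)
        little_n = Counter(c for k, c in enumerate(cols[j]) if k in set(rows) and c not in GAPPISH)
        n_total = sum(little_n.values())
        if n_total == 0:
            return 0.0
        order = sorted(N)
        m = _largest_remainder([N[a] for a in order], n_total)
        log_lambda = 0.0
        for a, m_a in zip(order, m):
            log_lambda += math.log(math.comb(N[a], little_n[a]))
            log_lambda -= math.log(math.comb(N[a], m_a))
        return max(-log_lambda, 0.0)

    return {
        (i, j): (directed(i, j) + directed(j, i)) / 2
        for i, j in combinations(range(n), 2)
    }


def oracle_mi(aln) -> dict[tuple[int, int], float]:
    cols = _cols(aln)
    out = {}
    for i, j in combinations(range(len(cols)), 2):
        pairs = [
            (a, b)
            for a, b in zip(cols[i], cols[j])
            if a not in GAPPISH and b not in GAPPISH
        ]
        n = len(pairs)
        if n < 2:
            out[(i, j)] = 0.0
            continue
        joint = Counter(pairs)
        pi = Counter(a for a, _ in pairs)
        pj = Counter(b for _, b in pairs)
        mi = 0.0
        for (a, b), c in joint.items():
            p_ab = c / n
            mi += p_ab * math.log(p_ab / ((pi[a] / n) * (pj[b] / n)))
        out[(i, j)] = mi
    return out


def oracle_re(aln, bg) -> list[float]:
    out = []
    for col in _cols(aln):
        residues = [c for c in col if c not in GAPPISH]
        if not residues:
            out.append(0.0)
            continue
        n = len(residues)
        re = 0.0
        for a in set(residues):
            p = residues.count(a) / n
            re += p * math.log(p / bg[a])
        out.append(re)
    return out
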