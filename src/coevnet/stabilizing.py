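"""Consensus-guided prediction of stabilizing mutations.

For a mutation-defined sub-alignment, candidate stabilizing substitutions
are positions that are well conserved within the sub-alignment (high
relative entropy) yet not entangled in strong pairwise coupling (low
mutual information), and whose reference residue differs from the full
alignment's consensus.  The proposed substitution is toward that
full-alignment consensus, written e.g. ``F1257L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import Alignment, ReferenceMap
from .covariance import mutual_information, relative_entropy
from .matrices import AMINO_ACIDS, BackgroundFrequencies, GAP_CODE, N_AA


@dataclass(frozen=True)
class StabilizingCandidate:
    """One proposed stabilizing substitution."""

    position: int
    ref_aa: str
    proposed_aa: str
    re: float
    rank: int

    @property
    def notation(self) -> str:
        return f"{self.ref_aa}{self.position}{self.proposed_aa}"


def column_consensus(aln: Alignment) -> list[str | None]:
    """Most frequent residue per column, gaps excluded.

    Ties break alphabetically; all-gap columns yield ``None``.
    """
    enc = aln.encoded
    out: list[str | None] = []
    for j in range(aln.n_cols):
        col = enc[:, j]
        col = col[col < GAP_CODE]
        if col.size == 0:
            out.append(None)
            continue
        counts = np.bincount(col, minlength=N_AA)
        out.append(AMINO_ACIDS[int(counts.argmax())])  # argmax ties -> lowest index, i.e. alphabetical
    return out


def predict_stabilizing(
    subset: Alignment,
    full: Alignment,
    rmap: ReferenceMap,
    bg: BackgroundFrequencies | None = None,
    max_gap_frac: float = 0.35,
    max_conservation: float = 0.95,
    mi_top_frac: float = 0.01,
) -> list[StabilizingCandidate]:
    """Run the conservation/correlation filter pipeline on ``subset``.

    Steps, applied to the sub-alignment: (1) drop gap-rich columns
    (> ``max_gap_frac``); (2) drop near-invariant columns (top-residue
    frequency > ``max_conservation``); (3) compute per-column RE and
    pairwise MI on the survivors; (4) drop columns with below-mean RE;
    (5) remove both members of every pair whose MI ranks in the top
    ``mi_top_frac`` of the (n^2-n)/2 pairs (potential hidden coupling);
    (6) collapse the surviving pairs to positions in MI-descending order,
    de-duplicating on first occurrence; (7) order positions by RE
    descending; (8) drop positions whose reference residue already equals
    the full-alignment consensus, and emit the rest as candidates.
    """
    if bg is None:
        bg = BackgroundFrequencies.yeast()
    if subset.n_cols != full.n_cols:
        raise ValueError("subset and full alignment must share columns")
    positions = rmap.positions
    ref_row = full.rows[full.seq_ids.index(rmap.ref_seq_id)]
    consensus = column_consensus(full)

    enc = subset.encoded
    n_cols = subset.n_cols

    # (1) gap filter, (2) conservation filter — strict inequalities
    gap_frac = subset.gap_fraction()
    cols = []
    for j in range(n_cols):
        if gap_frac[j] > max_gap_frac:
            continue
        col = enc[:, j]
        res = col[col < GAP_CODE]
        if res.size == 0:
            continue
        top_frac = np.bincount(res, minlength=N_AA).max() / res.size
        if top_frac > max_conservation:
            continue
        cols.append(j)
    if not cols:
        return []

    filtered = subset.take_columns(cols)
    # (3) RE and MI on the filtered column set
    re_scores = relative_entropy(filtered, bg)
    mi = mutual_information(filtered)

    # (4) below-mean RE columns out; mean over the filtered set
    mean_re = float(re_scores.values[re_scores.valid].mean())
    keep = [k for k in range(len(cols)) if re_scores.valid[k] and re_scores.values[k] >= mean_re]
    if not keep:
        return []

    # pairs among surviving columns, ranked by MI descending
    pairs = []
    for ai, a in enumerate(keep):
        for b in keep[ai + 1:]:
            pairs.append((a, b, float(mi.scores[a, b])))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))

    # (5) hidden-coupling exclusion: drop both members of top-MI pairs
    n_pos = len(keep)
    n_pairs = n_pos * (n_pos - 1) // 2
    n_remove = math.ceil(mi_top_frac * n_pairs)
    banned: set[int] = set()
    for a, b, _ in pairs[:n_remove]:
        banned.add(a)
        banned.add(b)
    surviving = [(a, b, s) for a, b, s in pairs[n_remove:]
                 if a not in banned and b not in banned]

    # (6) collapse to positions, higher residue number first, MI order kept
    ordered: list[int] = []
    seen: set[int] = set()
    for a, b, _ in surviving:
        hi, lo = (a, b) if positions[cols[a]] >= positions[cols[b]] else (b, a)
        for k in (hi, lo):
            if k not in seen:
                seen.add(k)
                ordered.append(k)

    # (7) final order by sub-alignment RE descending (stable)
    ordered.sort(key=lambda k: (-re_scores.values[k], positions[cols[k]]))

    # (8) consensus check and emission
    out: list[StabilizingCandidate] = []
    for k in ordered:
        j = cols[k]
        ref_aa = ref_row[j]
        cons = consensus[j]
        if cons is None or ref_aa == cons:
            continue
        out.append(StabilizingCandidate(int(positions[j]), ref_aa, cons,
                                        float(re_scores.values[k]), rank=len(out) + 1))
    return out


def write_candidates(cands: list[StabilizingCandidate], path: str | Path) -> None:
    lines = ["rank\tnotation\tposition\tref_aa\tconsensus_aa\tre"]
    for c in cands:
        lines.append(f"{c.rank}\t{c.notation}\t{c.position}\t{c.ref_aa}\t{c.proposed_aa}\t{c.re:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
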