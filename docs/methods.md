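# Methods

This note documents the models and procedures `coevnet` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Alignment model and curation

An alignment is a rectangular matrix of uppercase rows over the 20 standard
amino acids, `-` (gap) and `X` (unknown). `X` keeps its textual identity
but counts as a gap in every frequency computation, because it carries no
residue information. Curation proceeds in a fixed order:

1. **Length band** — rows are kept when their ungapped length lies in
   [245, 265] residues (inclusive; both bounds configurable). This targets
   single-domain sequences of the expected size and discards fragments and
   fusions.
2. **Reference numbering** — columns where a designated reference row is
   gapped are removed; the k-th surviving column maps to residue number
   `ref_start + k − 1`. `ref_start` defaults to 1207, the first resolved
   NBD2 residue in the ATP-free CFTR cryo-EM structure, and is deliberately
   a configuration value: the correct value depends on which residue the
   reference row starts at, which no alignment records internally.
3. **Gap-rich columns** — columns whose gap fraction strictly exceeds 0.35
   are dropped. Strict inequalities are used wherever a threshold is
   phrased as "more than"; the boundary cases (exactly 35% gaps, exactly
   245/265 residues, scores exactly at the noise cutoff, distances exactly
   8 Å) are all pinned by unit tests.

Perturbation sub-alignments are the rows carrying a specified residue at a
specified reference position — the sub-population in which a
mutation-specific coupling network can be probed. The pipeline skips
perturbations with fewer than 50 rows (configurable): the coupling
statistics are count-based and unstable below a few dozen sequences, and
runs on sub-alignments an order of magnitude smaller than the family are
better treated as unusable than silently reported.

## Coupling statistics

All logarithms are natural. For a pair of columns, frequency computations
use only rows un-gapped at both columns unless stated otherwise.

**OMES.** Score = Σ_L (N_obs − N_ex)²/N_valid over the list L of residue
pairs *observed at least once* at the column pair, with
N_ex = p(x_i)·p(y_j)·N_valid. Summing over observed pairs only (rather
than all 400) matters: unobserved pairs with nonzero expectation would
otherwise contribute. Pairs with fewer than two valid rows score 0.

**McBASC.** For column i an N×N array S_i holds the McLachlan (1972)
similarity of every sequence pair's residues at i, 0 when either is
gapped; the score is the absolute Pearson correlation of S_i and S_j over
all N² entries (diagonal included). The defining formula is a correlation
coefficient — the product of the two deviation terms divided by both
standard deviations. A column with zero variance (fully conserved, or
effectively so) makes the correlation undefined; such pairs receive the
sentinel value 2 and are then remapped to 0, so conserved columns drop out
of the ranking. The McLachlan matrix is taken from Biopython's
`substitution_matrices`; an identity matrix is available for closed-form
checks.

**SCA** (perturbation form). ΔΔG_{i,j} = Σ_x (ln[P^x_{i|δj}/P^x_{MSA|δj}]
− ln[P^x_i/P^x_MSA])², where P^x_i is the frequency of residue x at column
i, P^x_MSA the frequency of x pooled over *all* columns of the relevant
alignment, and the δj-conditioned quantities are the same computed on the
sub-alignment of rows carrying j's most frequent residue. Choices that the
defining equations leave open, exposed as configuration:

- *Perturbation residue*: the most frequent residue at j (ties broken
  alphabetically).
- *Pseudofrequency*: zero frequencies are floored at 1/(2·N_rows) of the
  relevant alignment, the natural "less than half a count" floor; without
  it the log-ratios diverge.
- *Minimum sub-alignment size* (`min_subset`, default 5): smaller
  perturbations flag their pairs invalid (scored 0) rather than raising.
- *Symmetrization*: the directed matrix is averaged with its transpose.
- Columns with gap frequency above 0.2 are excluded entirely.

**ELSC.** The perturbation at i keeps the rows carrying i's most frequent
residue (C_sub). For each other column j, with N_r the full-column residue
counts and n_r the subset counts (rows gapped at j excluded from both),
the directed score is −ln Π_r C(N_r, n_r)/C(N_r, m_r), where the model
composition m is n_total distributed proportionally to N_r and integerized
by largest-remainder rounding (ties to the alphabetically first residue).
Largest-remainder m is not always the exact mode of the multivariate
hypergeometric, so the raw score can be negative by a hair; directed scores
are floored at 0, preserving the intended semantics (the observed subset is
never *more* likely than the model). The matrix is symmetrized by averaging
the two directions. Binomial coefficients are evaluated as log-gamma
differences, exact to float precision at any alignment size.

**MI and RE.** Mutual information uses the joint residue distribution over
valid rows with 0·ln 0 ≡ 0. Relative entropy (conservation) compares a
column's residue frequencies against background frequencies q(x) — by
default the *S. cerevisiae* proteome composition, normalised at load; a
uniform 1/20 background is available and is used in closed-form tests
(fully conserved column → ln 20).

Every statistic is checked against an independently written brute-force
oracle (pure-Python loops over character columns, transcribing the
formulas directly) on randomized alignments up to 8×6 over a 4-letter
alphabet with gaps, via both a hypothesis sweep and fixed seeds.

## Null models and z-scores

**Scrambling** permutes each column independently across rows: per-column
composition — and therefore consensus, conservation and RE — is preserved
exactly while all inter-column dependence is destroyed. The **noise
baseline** for an algorithm is the mean over replicates (default 10) of
each scrambled replicate's maximum pair score; observed scores at or below
the cutoff (inclusive) are set to 0. Each replicate re-scrambles every
column independently.

**Stratified subsampling** draws n rows without replacement with per-taxon
counts apportioned by largest remainder, preserving the taxon ratio of the
source to within rounding.

**Z-scores** standardize the valid upper-triangle scores to mean 0 and
population (1/n) standard deviation 1. The population convention is a
deliberate configuration default: the scores are the complete population
of pairs, not a sample from a larger one. A z above 4 corresponds to an
upper-tail Gaussian probability of 3.2×10⁻⁵, below the 10⁻⁴ significance
convention used for coupling calls.

## Networks

The top-N (default 200) highest-scoring valid pairs form a weighted
undirected network; ties at the boundary break lexicographically by
(smaller, larger) position so outputs are bit-reproducible. Networks built
after baseline zeroing can contain zero-weight edges if fewer than N pairs
survive the cutoff; at realistic alignment sizes far more than N pairs
survive. "Central nodes" are the top-k (default 3) positions by degree
together with every position tying the k-th degree — the full tie is
reported because a handful-of-named-positions convention hides ties.
Composite maps intersect edge sets across algorithms, keeping every
algorithm's weight for provenance. Eigenvector centrality is the
Euclidean-normalised leading eigenvector of the unweighted adjacency
matrix, computed by power iteration on the largest connected component
(other components score 0); it is cross-checked against a dense
eigendecomposition in tests.

## Structure

Residues are represented by their Cβ atom, with Cα for glycine (which has
no Cβ) — the standard fallback. Only the first model of a PDB file is
read; altloc resolves to the highest-occupancy conformer; insertion codes
are rejected; unresolved residues are simply absent (no imputation).
Contacts use the 8 Å cutoff, inclusive. The score–distance join excludes
pairs separated by ≤8 sequence positions (local contacts trivially
co-vary) and positions with under 65% ungapped rows; because the median
distance could be read as pre- or post-filter, the summary reports both
(`median_retained_A`, `median_unfiltered_A`) and uses the retained median
for the power statistic. That statistic counts how many of the top-75
scoring retained pairs lie at or below the median and reports the
Binomial(75, ½) upper-tail probability, computed in exact rational
arithmetic before conversion to float. Backbone RMSD uses Kabsch
superposition (via Biopython's SVD superimposer) over the N/CA/C/O atoms
of residues present in both structures.

## Stabilizing-mutation prediction

For a perturbation sub-alignment the filter pipeline runs in order:
drop columns with >35% gaps; drop columns with top-residue frequency >95%
(no information for MI); compute RE and MI on the survivors; drop columns
with below-mean RE (the mean over that same filtered set); remove **both**
members of every pair whose MI ranks in the top 1% of the (n²−n)/2 pairs —
n being the filtered position count, not a fixed constant — as potential
hidden coupling; collapse surviving pairs to positions in MI-descending
order (higher residue number first), de-duplicating on first occurrence;
order the result by RE descending; and finally drop positions whose
reference residue already equals the full-alignment consensus. Candidates
are emitted as reference-residue + position + consensus-residue (e.g.
`F1257L`): the proposed substitution is toward the *full-MSA* consensus,
which is what makes it a candidate for restoring native-like coupling.
The number of banned pairs is ceil(0.01·pairs), so at least one pair is
always removed when any pairs exist.

## Synthetic data

The generator emulates a dereplicated protein-family alignment: each
column draws independently from a profile with a designated top residue at
probability c (the conservation) and the rest uniform; gaps are injected
independently per cell (default rate 0.02); taxon labels follow a fixed
distribution (animal/fungi/plant/protist/bacteria at 40/30/15/10/5%,
mirroring a eukaryote-dominated homolog set). A planted pair is a mixture:
with probability equal to the coupling strength the two residues are drawn
jointly from a pair table (default: a random residue bijection with
uniform weights, giving expected MI → ln 20 at full coupling; a 2-state
table gives ln 2), otherwise independently. A pair may be conditioned on a
"mutation column" residue so the coupling exists only in that
sub-population — the ground-truth analogue of a mutation-specific network.
Coupling-as-mixture was chosen over a Potts model because it is
analytically tractable (closed-form expected MI) and sufficient for
rank-recovery testing.

What this does **not** model: phylogenetic correlation between rows
(shared ancestry inflates apparent coupling in real families), column-level
gap clustering, and profile mixtures beyond top-plus-uniform. Passing the
synthetic benchmarks therefore demonstrates statistical power and
correctness of the machinery under independence, not robustness to
phylogenetic confounding.

Study-scale experiment sizes (in `coevnet.experiments`) were chosen to
exercise the statistics well inside their operating range: the power
benchmark uses 100 seeded alignments of 500 sequences × 60 columns with a
uniform background and one pair at coupling 0.9; perturbation specificity
uses 20 alignments of 1000 rows with a half-and-half mutation column; the
subsample-overlap experiment uses one 4000-row alignment with five planted
pairs (couplings 0.9–0.3) subsampled in triplicate to 2000/1000/500 rows
with taxon stratification. Toy structures place requested contact pairs
4–8 Å apart and everything else ≥12 Å apart by rejection sampling, so
contact classification has an exact ground truth.

## Known limitations

- SCA is implemented in its printed perturbation-frequency form, not the
  original binomial-density formulation; the two differ numerically.
- Whether OMES probabilities should be taken over valid rows or all rows
  is ambiguous in legacy implementations; valid rows is asserted here.
- No average-product correction or direct-coupling analysis; MI is raw.
- CD-HIT-style identity dereplication is not reimplemented; the generator
  produces effectively dereplicated rows by construction.
- Real-structure checks require user-supplied PDB files (nothing is
  downloaded); without them those tests skip.
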