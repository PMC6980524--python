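# coevnet

Amino-acid co-evolution analysis of protein multiple sequence alignments
(MSAs): pairwise column coupling scores, scrambled-alignment noise
baselines, mutation-defined perturbation sub-alignments, coupling-network
construction, structural validation against Cβ–Cβ distances, and
consensus-guided prediction of stabilizing mutations.

## The problem

Residue pairs that co-vary across a protein family are candidates for
structural or functional ("energetic") coupling. Given an aligned family —
the motivating case is the second nucleotide-binding domain (NBD2) of the
CFTR chloride channel, ~250 columns numbered from residue 1207 — one wants
to know: which column pairs are coupled beyond evolutionary noise, how does
the coupling network change in the sub-population of sequences carrying a
disease-associated substitution ("perturbation"), do coupled pairs sit
close in 3D structure, and which substitutions toward the family consensus
might stabilize a perturbed network?

`coevnet` implements that whole analysis as a tested library with a CLI and
a set of numbered analysis drivers, using a synthetic-MSA generator with
planted, ground-truth couplings in place of a database-derived alignment.

## The statistics

For columns *i*, *j* of an alignment (gaps and `X` excluded from counts;
pair statistics use rows un-gapped at both columns):

- **OMES** — Σ over observed residue pairs of (N_obs − N_ex)²/N_valid,
  with N_ex = p(x_i)·p(y_j)·N_valid.
- **McBASC** — |r_ij|, the Pearson correlation of the two columns' N×N
  McLachlan similarity arrays S_ikl; zero-variance (conserved/degenerate)
  columns receive the sentinel 2, remapped to 0.
- **SCA** — ΔΔG_ij = Σ_x (ln[P^x_{i|δj}/P^x_{MSA|δj}] − ln[P^x_i/P^x_MSA])²,
  the squared change of log frequency ratios under the perturbation δj that
  keeps rows carrying j's most frequent residue.
- **ELSC** — −ln Λ_j^⟨i⟩ with Λ = Π_r C(N_rj, n_rj)/C(N_rj, m_rj), comparing
  the subset composition n against a proportionally rounded model m.
- **MI** — Σ p(x,y) ln[p(x,y)/(p(x)p(y))] (nats); **RE** — per-column
  Kullback–Leibler divergence Σ p(x) ln[p(x)/q(x)] from background residue
  frequencies (yeast proteome by default).

Noise control: each column is independently permuted across rows
("scrambling"), preserving composition but destroying coupling; the mean of
per-replicate maximum scores is the cutoff, and observed scores at or below
it are zeroed. Networks take the top-200 surviving pairs as edges;
composite maps intersect the per-algorithm networks; central nodes are the
highest-degree positions. Structural validation counts how many of an
algorithm's top-75 pairs fall at or below the median Cβ–Cβ distance and
converts the count to a Binomial(75, ½) tail probability. Stabilizing
candidates are sub-alignment positions with above-mean RE, no top-1% MI
coupling, and a reference residue differing from the full-MSA consensus.

## Worked example

```python
from coevnet import (PlantedPair, SyntheticSpec, generate_coupled_msa,
                     mutual_information, scrambled_baseline, apply_baseline,
                     top_pairs)

spec = SyntheticSpec(n_seqs=500, n_cols=60, conservation=0.05,
                     planted_pairs=[PlantedPair(10, 40, 0.9)], seed=1)
aln, truth = generate_coupled_msa(spec)

sm = mutual_information(aln)
nb = scrambled_baseline(aln, "mi", n_replicates=10, seed=1)
net = top_pairs(apply_baseline(sm, nb), 200)
print(round(sm.scores[10, 40], 3), round(nb.cutoff, 3), (10, 40) in net.edges)
```

prints

```
2.596 0.531 True
```

— the planted pair carries ≈2.6 nats of mutual information, far above the
scrambled-noise cutoff of ≈0.53, and survives into the top-200 coupling
network.

The full analysis runs as numbered drivers:

```bash
python analysis/01_simulate.py --seed 1   # synthetic MSA + taxa + toy structure
python analysis/02_score.py    --seed 1   # all coupling scores, baselines, z-scores
python analysis/03_networks.py --seed 1   # top-200 networks, composite, centrality
python analysis/04_structure.py --seed 1  # distance join, contacts, binomial power
python analysis/05_stabilize.py --seed 1  # perturbation subset + stabilizing candidates
```

each printing what it found and writing tables under `results/`. A single
`coevnet` CLI (`curate`, `score`, `baseline`, `network`, `structure`,
`stabilize`, `simulate`, `run`) wraps the same library for real alignments;
`coevnet run --config run.yaml` executes the end-to-end pipeline.

Structure files are user-supplied (the package never downloads); tests that
check published CFTR structure values look for PDB files under `data/pdb/`
and are skipped when absent.

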