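import math
from collections import Counter

import numpy as np
import pytest

from coevnet import (
    ScoreMatrix,
    apply_baseline,
    mutual_information,
    omes,
    pairwise_zscores,
    relative_entropy,
    scramble_columns,
    scrambled_baseline,
    stratified_subsample,
)
from coevnet.matrices import BackgroundFrequencies
from coevnet.null_models import NoiseBaseline
from coevnet.synthetic import PlantedPair, SyntheticSpec, generate_coupled_msa

from conftest import aln_from_cols


@pytest.fixture(scope="module")
def coupled_msa():
    spec = SyntheticSpec(n_seqs=300, n_cols=20, conservation=0.3, gap_rate=0.03,
                         planted_pairs=[PlantedPair(4, 15, 1.0)], seed=11)
    aln, _ = generate_coupled_msa(spec)
    return aln


class TestScrambling:
    def test_column_composition_preserved(self, coupled_msa):
        scr = scramble_columns(coupled_msa, seed=5)
        for j in range(coupled_msa.n_cols):
            assert Counter(scr.column(j)) == Counter(coupled_msa.column(j))

    def test_per_column_re_invariant_under_scrambling(self, coupled_msa):
        bg = BackgroundFrequencies.yeast()
        before = relative_entropy(coupled_msa, bg).values
        after = relative_entropy(scramble_columns(coupled_msa, 5), bg).values
        assert np.allclose(before, after)

    def test_seed_determinism(self, coupled_msa):
        a = scramble_columns(coupled_msa, 42)
        b = scramble_columns(coupled_msa, 42)
        c = scramble_columns(coupled_msa, 43)
        assert a.rows == b.rows
        assert a.rows != c.rows

    def test_scrambling_destroys_planted_coupling(self, coupled_msa):
        before = mutual_information(coupled_msa).scores[4, 15]
        after = mutual_information(scramble_columns(coupled_msa, 7)).scores[4, 15]
        # the planted deterministic pair carries ~ln 20 nats of MI; scrambling
        # pushes it to the finite-sample noise floor (~(19*19)/(2N) nats)
        assert before > 3 * after


class TestBaseline:
    def test_single_replicate_cutoff_is_its_maximum(self, coupled_msa):
        nb = scrambled_baseline(coupled_msa, "mi", n_replicates=1, seed=0)
        assert nb.cutoff == nb.replicate_maxima[0]

    def test_constant_alignment_zero_cutoff(self):
        aln = aln_from_cols("AAAA", "CCCC", "DDDD")
        for alg in ("omes", "mi"):
            nb = scrambled_baseline(aln, alg, n_replicates=3, seed=0)
            assert nb.cutoff == 0.0

    def test_unknown_algorithm_rejected(self, coupled_msa):
        with pytest.raises(ValueError, match="unknown algorithm"):
            scrambled_baseline(coupled_msa, "nonsense", 2, 0)

    def test_cutoff_reproducible_and_le_max(self, coupled_msa):
        a = scrambled_baseline(coupled_msa, "omes", n_replicates=4, seed=9)
        b = scrambled_baseline(coupled_msa, "omes", n_replicates=4, seed=9)
        assert a.replicate_maxima == b.replicate_maxima
        assert a.cutoff <= max(a.replicate_maxima)

    def test_json_round_trip(self, tmp_path, coupled_msa):
        import json
        nb = scrambled_baseline(coupled_msa, "mi", n_replicates=2, seed=1)
        nb.to_json(tmp_path / "b.json")
        data = json.loads((tmp_path / "b.json").read_text())
        assert data["algorithm"] == "mi"
        assert data["cutoff"] == pytest.approx(nb.cutoff)


class TestApplyBaseline:
    def _sm(self, values):
        n = 3
        scores = np.zeros((n, n))
        scores[0, 1] = scores[1, 0] = values[0]
        scores[0, 2] = scores[2, 0] = values[1]
        scores[1, 2] = scores[2, 1] = values[2]
        return ScoreMatrix("mi", np.arange(n), scores, np.ones(n, bool))

    def test_cutoff_is_inclusive(self):
        sm = self._sm([27.2, 30.0, 10.0])
        nb = NoiseBaseline("mi", [27.2], seed=0)
        out = apply_baseline(sm, nb)
        assert out.scores[0, 1] == 0.0      # equal to cutoff -> zeroed
        assert out.scores[0, 2] == 30.0     # above -> untouched
        assert out.scores[1, 2] == 0.0

    def test_zero_cutoff_keeps_positive_scores(self):
        sm = self._sm([1.0, 2.0, 0.0])
        out = apply_baseline(sm, NoiseBaseline("mi", [0.0], seed=0))
        assert out.scores[0, 1] == 1.0 and out.scores[0, 2] == 2.0
        assert out.scores[1, 2] == 0.0

    def test_all_below_gives_zero_matrix(self):
        sm = self._sm([1.0, 2.0, 3.0])
        out = apply_baseline(sm, NoiseBaseline("mi", [99.0], seed=0))
        assert (out.scores == 0).all()

    def test_idempotent(self):
        sm = self._sm([27.2, 30.0, 10.0])
        nb = NoiseBaseline("mi", [27.2], seed=0)
        once = apply_baseline(sm, nb)
        twice = apply_baseline(once, nb)
        assert np.array_equal(once.scores, twice.scores)

    def test_tag_mismatch_raises(self):
        sm = self._sm([1, 2, 3])
        with pytest.raises(ValueError, match="mismatch"):
            apply_baseline(sm, NoiseBaseline("omes", [0.5], seed=0))


class TestStratifiedSubsample:
    def _aln(self, labels):
        n = len(labels)
        return aln_from_cols("A" * n, "C" * n, taxon=list(labels))

    def test_even_split(self):
        aln = self._aln(["animal"] * 10 + ["fungi"] * 10)
        sub = stratified_subsample(aln, 10, seed=0)
        assert Counter(sub.taxon) == {"animal": 5, "fungi": 5}

    def test_largest_remainder_60_30_10(self):
        aln = self._aln(["animal"] * 60 + ["fungi"] * 30 + ["plant"] * 10)
        sub = stratified_subsample(aln, 10, seed=1)
        assert Counter(sub.taxon) == {"animal": 6, "fungi": 3, "plant": 1}

    def test_full_size_is_permutation(self):
        aln = self._aln(["animal"] * 7 + ["fungi"] * 3)
        sub = stratified_subsample(aln, 10, seed=2)
        assert sorted(sub.seq_ids) == sorted(aln.seq_ids)

    def test_nested_subsample_preserves_ratios(self):
        aln = self._aln(["animal"] * 50 + ["fungi"] * 30 + ["plant"] * 20)
        sub1 = stratified_subsample(aln, 50, seed=3)
        sub2 = stratified_subsample(sub1, 10, seed=4)
        assert Counter(sub2.taxon) == {"animal": 5, "fungi": 3, "plant": 2}

    def test_missing_taxa_raises(self):
        aln = aln_from_cols("AA", "CC")
        with pytest.raises(ValueError, match="taxon"):
            stratified_subsample(aln, 1, seed=0)


class TestZScores:
    def test_three_score_example(self):
        scores = np.zeros((3, 3))
        scores[0, 1] = scores[1, 0] = 1.0
        scores[0, 2] = scores[2, 0] = 2.0
        scores[1, 2] = scores[2, 1] = 3.0
        sm = ScoreMatrix("omes", np.arange(3), scores, np.ones(3, bool))
        z = pairwise_zscores(sm)
        assert z.scores[1, 2] == pytest.approx((3 - 2) / math.sqrt(2 / 3))

    def test_output_normalised(self, coupled_msa):
        z = pairwise_zscores(omes(coupled_msa))
        vals = z.pair_values()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_strong_pair_exceeds_significance_bar(self, coupled_msa):
        # a deterministic planted pair sits far out in the upper tail
        z = pairwise_zscores(mutual_information(coupled_msa))
        assert z.scores[4, 15] >= 4.0

    def test_zero_variance_raises(self):
        scores = np.ones((3, 3))
        sm = ScoreMatrix("omes", np.arange(3), scores, np.ones(3, bool))
        with pytest.raises(ValueError, match="variance"):
            pairwise_zscores(sm)
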