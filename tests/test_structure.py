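import math

import numpy as np
import pytest

from coevnet import (
    DistanceMatrix,
    ResidueCoordinates,
    ScoreMatrix,
    binomial_pvalue,
    classify_contacts,
    generate_toy_coordinates,
    kabsch_rmsd,
    pairwise_distances,
    read_cbeta_coordinates,
    score_distance_table,
    write_pdb,
)

def _atom(serial, name, resname, resnum, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} A{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


# a 3-residue peptide: ALA (has CB), GLY (no CB), ALA with full backbone
TINY_PDB = "\n".join([
    _atom(1, " N", "ALA", 1, 0.000, 0.000, 0.000, "N"),
    _atom(2, " CA", "ALA", 1, 1.458, 0.000, 0.000, "C"),
    _atom(3, " C", "ALA", 1, 2.009, 1.420, 0.000, "C"),
    _atom(4, " O", "ALA", 1, 1.251, 2.390, 0.000, "O"),
    _atom(5, " CB", "ALA", 1, 2.000, -0.800, -1.200, "C"),
    _atom(6, " N", "GLY", 2, 3.332, 1.536, 0.000, "N"),
    _atom(7, " CA", "GLY", 2, 4.000, 2.800, 0.300, "C"),
    _atom(8, " C", "GLY", 2, 5.500, 2.700, 0.200, "C"),
    _atom(9, " O", "GLY", 2, 6.100, 1.650, 0.100, "O"),
    _atom(10, " N", "ALA", 3, 6.150, 3.850, 0.250, "N"),
    _atom(11, " CA", "ALA", 3, 7.600, 3.900, 0.200, "C"),
    _atom(12, " C", "ALA", 3, 8.200, 5.300, 0.300, "C"),
    _atom(13, " O", "ALA", 3, 7.500, 6.300, 0.400, "O"),
    _atom(14, " CB", "ALA", 3, 8.300, 3.100, 1.300, "C"),
    "END",
]) + "\n"


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


class TestCoordinateReading:
    def test_cb_preferred_over_ca(self, tiny_pdb):
        rc = read_cbeta_coordinates(tiny_pdb, "A")
        assert np.allclose(rc.coords[1], [2.0, -0.8, -1.2])

    def test_glycine_falls_back_to_ca(self, tiny_pdb):
        rc = read_cbeta_coordinates(tiny_pdb, "A")
        assert np.allclose(rc.coords[2], [4.0, 2.8, 0.3])

    def test_unresolved_residue_simply_absent(self, tiny_pdb):
        rc = read_cbeta_coordinates(tiny_pdb, "A", (1, 10))
        assert rc.residues == [1, 2, 3]  # 4..10 not in the model, no error

    def test_range_restriction(self, tiny_pdb):
        rc = read_cbeta_coordinates(tiny_pdb, "A", (2, 3))
        assert rc.residues == [2, 3]

    def test_empty_selection_raises(self, tiny_pdb):
        with pytest.raises(ValueError, match="no residues"):
            read_cbeta_coordinates(tiny_pdb, "A", (50, 60))

    def test_missing_chain_raises(self, tiny_pdb):
        with pytest.raises(ValueError, match="chain"):
            read_cbeta_coordinates(tiny_pdb, "B")

    def test_toy_pdb_round_trip(self, tmp_path):
        rc = generate_toy_coordinates(5, [(1, 4)], seed=0)
        path = tmp_path / "toy.pdb"
        write_pdb(rc, path)
        back = read_cbeta_coordinates(path, "A")
        assert back.residues == rc.residues
        for r in rc.residues:
            assert np.allclose(back.coords[r], rc.coords[r], atol=1e-3)


class TestDistances:
    def test_three_four_five(self):
        rc = ResidueCoordinates({1: np.zeros(3), 2: np.array([3.0, 4.0, 0.0])})
        dm = pairwise_distances(rc)
        assert dm.distance(1, 2) == pytest.approx(5.0)

    def test_zero_diagonal_symmetry_triangle(self, rng):
        coords = {i + 1: rng.uniform(0, 50, 3) for i in range(8)}
        dm = pairwise_distances(ResidueCoordinates(coords))
        assert np.allclose(np.diag(dm.distances), 0)
        assert np.allclose(dm.distances, dm.distances.T)
        n = len(dm.positions)
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert dm.distances[a, c] <= dm.distances[a, b] + dm.distances[b, c] + 1e-9

    def test_single_residue_raises(self):
        with pytest.raises(ValueError):
            pairwise_distances(ResidueCoordinates({1: np.zeros(3)}))


class TestContacts:
    @pytest.mark.parametrize("d,expected", [(4.92, True), (8.0, True), (24.14, False)])
    def test_cutoff_inclusive(self, d, expected):
        rc = ResidueCoordinates({1: np.zeros(3), 2: np.array([d, 0.0, 0.0])})
        contacts = classify_contacts(pairwise_distances(rc))
        assert contacts[(1, 2)] is expected

    def test_toy_structure_recovers_requested_contacts(self):
        requested = [(1, 5), (2, 7)]
        rc = generate_toy_coordinates(8, requested, seed=1)
        contacts = classify_contacts(pairwise_distances(rc))
        found = {pair for pair, is_contact in contacts.items() if is_contact}
        assert found == set(requested)


class TestBinomial:
    @pytest.mark.parametrize("n,expected", [
        (0, 1.0),
        (38, 0.5),                # symmetry of Binomial(75, 1/2), odd trials
        (75, 0.5 ** 75),
    ])
    def test_exact_values(self, n, expected):
        assert binomial_pvalue(n, 75) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing(self):
        # exact arithmetic is strictly decreasing; in float, values within
        # eps of 1 collapse, so strictness is asserted where resolvable
        ps = [binomial_pvalue(n, 75) for n in range(76)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(a > b for a, b in zip(ps[15:], ps[16:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binomial_pvalue(76, 75)
        with pytest.raises(ValueError):
            binomial_pvalue(-1, 75)


class TestScoreDistanceTable:
    def _inputs(self):
        # positions 1207..1226, coordinates on a line 5 A apart
        positions = np.arange(1207, 1227)
        coords = {int(p): np.array([5.0 * k, 0.0, 0.0]) for k, p in enumerate(positions)}
        dm = pairwise_distances(ResidueCoordinates(coords))
        rng = np.random.default_rng(0)
        scores = rng.random((20, 20))
        scores = (scores + scores.T) / 2
        np.fill_diagonal(scores, 0)
        sm = ScoreMatrix("omes", positions, scores, np.ones(20, bool))
        return sm, dm

    def test_separation_filter_matches_brute_force(self):
        sm, dm = self._inputs()
        comp = score_distance_table(sm, dm, min_separation=8)
        expected_pairs = {
            (int(a), int(b))
            for a in sm.positions for b in sm.positions
            if a < b and abs(int(a) - int(b)) > 8
        }
        got = set(zip(comp.table.pos_i, comp.table.pos_j))
        assert got == expected_pairs

    @pytest.mark.parametrize("pi,pj,excluded", [
        (1250, 1255, True),   # separation 5: inside "within eight"
        (1250, 1258, True),   # separation 8: boundary, still excluded
        (1250, 1259, False),  # separation 9: retained
    ])
    def test_separation_boundary(self, pi, pj, excluded):
        coords = {pi: np.zeros(3), pj: np.array([10.0, 0, 0]),
                  1300: np.array([0, 30.0, 0]), 1400: np.array([0, 0, 30.0])}
        dm = pairwise_distances(ResidueCoordinates(coords))
        positions = np.array(sorted(coords))
        scores = np.ones((4, 4)); np.fill_diagonal(scores, 0)
        sm = ScoreMatrix("omes", positions, scores, np.ones(4, bool))
        comp = score_distance_table(sm, dm)
        got = set(zip(comp.table.pos_i, comp.table.pos_j))
        assert ((pi, pj) not in got) is excluded

    def test_gappy_position_excluded(self):
        sm, dm = self._inputs()
        ungapped = {int(p): 1.0 for p in sm.positions}
        ungapped[1220] = 0.60  # below the 65% rule
        comp = score_distance_table(sm, dm, ungapped_frac=ungapped)
        assert 1220 not in set(comp.table.pos_i) | set(comp.table.pos_j)

    def test_summary_counts_below_or_equal_median(self):
        sm, dm = self._inputs()
        comp = score_distance_table(sm, dm, top=10)
        ranked = comp.table.sort_values(
            ["score", "pos_i", "pos_j"], ascending=[False, True, True]).head(10)
        assert comp.n_below_median == (ranked.distance <= comp.median_retained).sum()
        assert comp.p_value == pytest.approx(binomial_pvalue(comp.n_below_median, 10))

    def test_empty_join_raises(self):
        sm, dm = self._inputs()
        with pytest.raises(ValueError, match="no pairs"):
            score_distance_table(sm, dm, min_separation=100)


class TestKabschRMSD:
    def _backbone(self, rng, n=6):
        coords, backbone = {}, {}
        for r in range(1, n + 1):
            base = rng.uniform(0, 30, 3)
            coords[r] = base
            backbone[r] = {a: base + rng.normal(0, 1, 3) for a in ("N", "CA", "C", "O")}
        return ResidueCoordinates(coords, backbone=backbone)

    def test_identical_structures_zero(self, rng):
        a = self._backbone(rng)
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        a = self._backbone(rng)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1]])
        t = np.array([5.0, -3.0, 12.0])
        b = ResidueCoordinates(
            {r: R @ xyz + t for r, xyz in a.coords.items()},
            backbone={r: {n: R @ v + t for n, v in bb.items()}
                      for r, bb in a.backbone.items()},
        )
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_known_displacement(self, rng):
        a = self._backbone(rng)
        # displace every atom by 2 A along +x after superposition is fixed:
        # a uniform translation is removed by the fit, so perturb one atom set
        b = ResidueCoordinates(
            dict(a.coords),
            backbone={r: {n: v + rng.normal(0, 0.5, 3) for n, v in bb.items()}
                      for r, bb in a.backbone.items()},
        )
        rms = kabsch_rmsd(a, b)
        assert 0 < rms < 2.0

    def test_too_few_common_residues(self, rng):
        a = self._backbone(rng, n=2)
        with pytest.raises(ValueError, match="common residues"):
            kabsch_rmsd(a, a)
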