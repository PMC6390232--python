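"""Segregation, map estimation, EM interval mapping, fine mapping."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import xlogy

from askit import simulate
from askit.linkage import (MISSING, Candidate, GeneticMap, Marker, N2Panel,
                           estimate_map, filter_candidates, find_recombinants,
                           haldane_d, haldane_r, interval_scan,
                           map_from_panel_positions, minimal_interval,
                           permutation_threshold, read_panel, write_panel,
                           _em_lod, _het_prior)
from askit.linkage import test_segregation as segregation_chi2


class TestSegregation:
    def test_perfect_ratio(self):
        chi2, p, frac = segregation_chi2(50, 100)
        assert chi2 == 0.0 and p == 1.0 and frac == 0.5

    def test_observed_counts_closed_form(self):
        """275/559: chi-square from the hand formula sum (O-E)^2/E."""
        chi2, p, _ = segregation_chi2(275, 559)
        e = 559 / 2
        expected = (275 - e) ** 2 / e + (284 - e) ** 2 / e
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert chi2 == pytest.approx(0.145, abs=5e-4)
        assert p == pytest.approx(0.70, abs=0.01)

    def test_total_distortion(self):
        chi2, p, _ = segregation_chi2(100, 100)
        assert chi2 == 100.0 and p < 1e-3

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            segregation_chi2(1, 0)


class TestHaldane:
    def test_round_trip_identity(self):
        d = np.linspace(0.01, 200.0, 500)
        assert np.allclose(haldane_d(haldane_r(d)), d, atol=1e-9)

    def test_known_value(self):
        assert haldane_d(0.1) == pytest.approx(-50 * np.log(0.8), abs=1e-9)
        assert haldane_d(0.1) == pytest.approx(11.157, abs=1e-3)


def panel_from_columns(columns, phenotype, chrom="1", spacing=10.0):
    cols = np.column_stack(columns).astype(np.int8)
    markers = [Marker(f"M{j + 1}", chrom, j * spacing)
               for j in range(cols.shape[1])]
    return N2Panel(markers, cols, np.asarray(phenotype, dtype=np.int8))


class TestEstimateMap:
    def test_identical_columns_zero_distance(self):
        g = np.array([0, 1, 1, 0, 1] * 4)
        panel = panel_from_columns([g, g], np.zeros(20))
        gmap = estimate_map(panel)
        assert list(gmap.positions["1"].values()) == [0.0, 0.0]

    def test_recombination_fraction_converts(self):
        # 2 recombinant of 20 -> r = 0.1 -> 11.157 cM
        g1 = np.array([0] * 10 + [1] * 10)
        g2 = g1.copy()
        g2[[0, 10]] ^= 1
        panel = panel_from_columns([g1, g2], np.zeros(20))
        gmap = estimate_map(panel)
        assert list(gmap.positions["1"].values())[1] == \
            pytest.approx(-50 * np.log(0.8), abs=1e-9)

    def test_unlinked_columns_capped(self, caplog):
        g1 = np.array([0, 1] * 10)
        g2 = np.array([1, 0] * 10)
        with caplog.at_level("WARNING"):
            gmap = estimate_map(panel_from_columns([g1, g2], np.zeros(20)))
        assert "capped" in caplog.text
        assert list(gmap.positions["1"].values())[1] == \
            pytest.approx(float(haldane_d(0.49)))

    def test_all_missing_marker_errors(self):
        g = np.array([0, 1] * 5)
        panel = panel_from_columns([g, np.full(10, MISSING)], np.zeros(10))
        with pytest.raises(ValueError, match="M2"):
            estimate_map(panel)


def brute_force_lod(prior, y):
    """Independent penetrance-likelihood maximization: exhaustive grid
    over (p1, p0) followed by a Nelder-Mead polish."""
    y = np.asarray(y, float)
    n = len(y)
    k = y.sum()
    pbar = k / n
    ll0 = xlogy(k, pbar) + xlogy(n - k, 1 - pbar)

    def nll(theta):
        p1, p0 = np.clip(theta, 0.0, 1.0)
        f1 = np.where(y == 1, p1, 1 - p1)
        f0 = np.where(y == 1, p0, 1 - p0)
        return -np.log(np.maximum(prior * f1 + (1 - prior) * f0,
                                  1e-300)).sum()

    grid = np.linspace(0.0, 1.0, 101)
    best, best_val = None, np.inf
    for p1 in grid:
        for p0 in grid:
            v = nll((p1, p0))
            if v < best_val:
                best, best_val = (p1, p0), v
    res = minimize(nll, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    return max(0.0, (-res.fun - ll0) / np.log(10))


class TestIntervalScan:
    def test_coincident_fully_penetrant_marker(self):
        """LOD at a coincident marker with phenotype == genotype and a
        50/50 split is n*log10(2) (saturated vs null closed form)."""
        g = np.array([1] * 50 + [0] * 50, dtype=np.int8)
        panel = panel_from_columns([g, g], g.copy())
        curve = interval_scan(panel, map_from_panel_positions(panel))
        assert curve.peak[2] == pytest.approx(100 * np.log10(2), abs=1e-6)

    def test_monomorphic_phenotype_zero(self):
        g = np.array([1, 0] * 10, dtype=np.int8)
        panel = panel_from_columns([g, g], np.zeros(20))
        curve = interval_scan(panel, map_from_panel_positions(panel))
        assert (curve.grid["lod"] == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_em_matches_brute_force(self, seed):
        """EM scan agrees with exhaustive penetrance-grid maximization
        (plus polish) to 1e-6 on small noisy panels."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 30))
        cols = [rng.integers(0, 2, n) for _ in range(3)]
        # imperfect penetrance and some missing genotypes
        y = np.where(rng.random(n) < 0.8, cols[1], rng.integers(0, 2, n))
        cols[0][rng.random(n) < 0.15] = MISSING
        panel = panel_from_columns(cols, y)
        gmap = map_from_panel_positions(panel)
        grid = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        prior = _het_prior(panel, gmap, "1", grid)
        lod = _em_lod(prior, y.astype(float),
                      starts=((0.8, 0.2), (0.2, 0.8), (0.6, 0.4)))
        for i in range(len(grid)):
            oracle = brute_force_lod(prior[i], y)
            assert lod[i] == pytest.approx(oracle, abs=1e-6), grid[i]

    def test_prior_interpolates_flanks(self):
        """Between discordant flanking markers the heterozygosity prior is
        strictly between 0 and 1 and equals the genotype at markers."""
        g1 = np.array([1, 0], dtype=np.int8)
        g2 = np.array([0, 0], dtype=np.int8)
        panel = panel_from_columns([g1, g2], [1, 0], spacing=20.0)
        gmap = map_from_panel_positions(panel)
        prior = _het_prior(panel, gmap, "1", np.array([0.0, 10.0, 20.0]))
        assert prior[0, 0] == 1.0 and prior[2, 0] == 0.0
        assert 0.0 < prior[1, 0] < 1.0
        # double-recombinant chance between two hom flanks is tiny, not 0
        assert prior[0, 1] == 0.0 and prior[2, 1] == 0.0
        assert prior[1, 1] < 0.05

    def test_missing_everywhere_gives_half_prior(self):
        g = np.full(4, MISSING, dtype=np.int8)
        panel = panel_from_columns([g, g], [1, 0, 1, 0])
        gmap = map_from_panel_positions(panel)
        prior = _het_prior(panel, gmap, "1", np.array([0.0, 10.0]))
        assert (prior == 0.5).all()


@pytest.fixture(scope="module")
def null_panel():
    rng = np.random.default_rng(8)
    cols = [rng.integers(0, 2, 60) for _ in range(8)]
    markers = [Marker(f"M{j}", str(1 + j // 4), (j % 4) * 15.0)
               for j in range(8)]
    return N2Panel(markers, np.column_stack(cols).astype(np.int8),
                   rng.integers(0, 2, 60).astype(np.int8))


class TestPermutationThreshold:
    def test_seed_determinism(self, null_panel):
        gmap = map_from_panel_positions(null_panel)
        t1 = permutation_threshold(null_panel, gmap, n_perm=100, seed=5)
        t2 = permutation_threshold(null_panel, gmap, n_perm=100, seed=5)
        assert t1 == t2

    def test_alpha_one_is_minimum_of_maxima(self, null_panel):
        gmap = map_from_panel_positions(null_panel)
        t = permutation_threshold(null_panel, gmap, n_perm=100, alpha=1.0,
                                  seed=5)
        t05 = permutation_threshold(null_panel, gmap, n_perm=100, alpha=0.05,
                                    seed=5)
        assert t <= t05

    def test_null_calibration(self):
        """With no causal locus, P(max LOD > threshold) is near alpha."""
        gmap = simulate.default_genome_map(n_chromosomes=8)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = simulate.SimConfig(seed=1000 + rep, n_individuals=60,
                                     penetrance=0.5, phenocopy_rate=0.5)
            panel = simulate.simulate_backcross(gmap, ("1", 40.0), cfg)
            curve = interval_scan(panel, gmap, step_cM=5.0,
                                  em_max_iter=60, em_tol=1e-6)
            thr = permutation_threshold(panel, gmap, n_perm=100, alpha=0.05,
                                        seed=rep, step_cM=5.0)
            hits += curve.max_lod > thr
        rate = hits / n_rep
        # 3 sigma Monte-Carlo band around 0.05
        assert 0.0 <= rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestRecombinants:
    def test_identical_columns_none(self):
        g = np.array([0, 1, 1, 0], dtype=np.int8)
        panel = panel_from_columns([g, g], [0, 1, 1, 0])
        assert find_recombinants(panel, "M1", "M2") == []

    def test_planted_recombinant_found(self):
        g1 = np.array([0, 1, 1, 0], dtype=np.int8)
        g2 = g1.copy()
        g2[2] ^= 1
        panel = panel_from_columns([g1, g2], [0, 1, 1, 0])
        assert find_recombinants(panel, "M1", "M2") == ["N2-3"]

    def test_missing_excluded(self):
        g1 = np.array([0, 1, MISSING, 0], dtype=np.int8)
        g2 = np.array([0, 0, 1, 0], dtype=np.int8)
        panel = panel_from_columns([g1, g2], [0, 1, 1, 0])
        assert find_recombinants(panel, "M1", "M2") == ["N2-2"]

    def test_cross_chromosome_errors(self):
        markers = [Marker("M1", "1", 0.0), Marker("M2", "2", 0.0)]
        panel = N2Panel(markers, np.zeros((3, 2), dtype=np.int8),
                        np.zeros(3, dtype=np.int8))
        with pytest.raises(ValueError, match="different chromosomes"):
            find_recombinants(panel, "M1", "M2")


class TestMinimalInterval:
    def region_panel(self, genotypes, phenotype):
        return panel_from_columns(
            [np.asarray(c, dtype=np.int8) for c in genotypes], phenotype,
            chrom="2", spacing=1.0)

    def test_recombinant_tightens_left_bound(self):
        # second mouse is phenotypic but het only right of M3, so the
        # causal position must lie right of M3
        g_cols = [[1, 0], [1, 0], [1, 0], [1, 1], [1, 1]]  # M1..M5
        panel = self.region_panel(g_cols, [1, 1])
        res = minimal_interval(panel, "2", (0.0, 4.0))
        assert res.left_marker == "M3"
        assert res.right_marker == "M5"

    def test_no_recombinants_full_region(self):
        g1 = np.array([1, 0, 1], dtype=np.int8)
        panel = self.region_panel([g1, g1, g1, g1], [1, 0, 1])
        res = minimal_interval(panel, "2", (0.0, 3.0))
        assert (res.left_marker, res.right_marker) == ("M1", "M4")

    def test_phenocopy_triggers_inconsistency(self):
        # individual 3 is phenotypic but recurrent-homozygous throughout
        cols = [np.array([1, 0, 1], dtype=np.int8) for _ in range(4)]
        cols = [c.copy() for c in cols]
        for c in cols:
            c[2] = 0
        panel = self.region_panel(cols, [1, 0, 1])
        res = minimal_interval(panel, "2", (0.0, 3.0))
        assert not res.consistent
        assert res.inconsistent_individuals == ["N2-3"]
        res2 = minimal_interval(panel, "2", (0.0, 3.0),
                                exclude_inconsistent=True)
        assert (res2.left_marker, res2.right_marker) == ("M1", "M4")

    def test_causal_containment_over_random_pedigrees(self):
        """The interval always contains the planted causal position under
        full penetrance and error-free genotyping, at the sub-cM marker
        spacing used for dense STR fine mapping (where double crossovers
        between adjacent markers are vanishingly rare)."""
        gmap = GeneticMap({"2": {f"M{j}": 0.125 * j for j in range(9)}})
        causal = 0.5625
        for rep in range(50):
            cfg = simulate.SimConfig(seed=300 + rep, n_individuals=100)
            panel = simulate.simulate_backcross(gmap, ("2", causal), cfg)
            res = minimal_interval(panel, "2", (0.0, 1.0))
            assert res.consistent
            assert res.left_cM <= causal <= res.right_cM


class TestCandidates:
    GENES = [f"g{i}" for i in range(21)]

    def test_threshold_filtering(self):
        """21 genes in the interval, 8 expressed above threshold."""
        table = {g: (5.0 if i < 8 else 0.1) for i, g in enumerate(self.GENES)}
        out = filter_candidates(self.GENES, table, 1.0)
        assert len(out) == 8

    def test_absent_gene_retained_flagged(self):
        out = filter_candidates(["a", "b"], {"a": 2.0}, 1.0)
        assert [c.gene for c in out] == ["a", "b"]
        assert out[1].unknown_expression

    def test_empty_and_zero_threshold(self):
        assert filter_candidates([], {}, 1.0) == []
        table = {g: 0.0 for g in self.GENES}
        assert len(filter_candidates(self.GENES, table, 0.0)) == 21


class TestPanelIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        cols = [rng.integers(0, 2, 12) for _ in range(4)]
        cols[1][3] = MISSING
        panel = panel_from_columns(cols, rng.integers(0, 2, 12))
        path = tmp_path / "panel.tsv"
        write_panel(panel, str(path))
        back = read_panel(str(path))
        assert back.markers == panel.markers
        assert (back.genotypes == panel.genotypes).all()
        assert (back.phenotype == panel.phenotype).all()
        assert back.individual_ids == panel.individual_ids
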