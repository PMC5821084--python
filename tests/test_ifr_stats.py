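import math

import numpy as np
import pytest

from tradistat import (
    GeneRecord,
    GenomeAnnotation,
    InsertionProfile,
    NullModelConfig,
    NullModelResult,
    critical_length,
    geometric_tail_p,
    longest_run_survival,
    poisson_tail_p,
    scan_ifrs,
    simulate_gene_null,
    simulate_genome_null,
)
from tradistat.ifr_stats import (
    TableRangeError,
    _maximal_zero_runs,
    longest_run_survival_curve,
)


def brute_force_geometric_tail(L, rho, kmax=20_000):
    k = np.arange(L, kmax + 1)
    return float((rho * (1 - rho) ** k).sum())


class TestGeometricTail:
    def test_full_mass_at_zero(self):
        assert geometric_tail_p(0, 0.3) == 1.0

    def test_closed_form(self):
        assert geometric_tail_p(2, 0.5) == pytest.approx(0.25)

    @pytest.mark.parametrize("rho", [0.05, 0.195, 0.5, 0.9])
    @pytest.mark.parametrize("L", [1, 10, 37, 75, 100])
    def test_matches_brute_force_summation(self, rho, L):
        assert geometric_tail_p(L, rho) == pytest.approx(
            brute_force_geometric_tail(L, rho), abs=1e-10
        )

    def test_strictly_decreasing_in_L_and_rho(self):
        for rho in (0.1, 0.3, 0.7):
            vals = [geometric_tail_p(L, rho) for L in range(0, 50)]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        for L in (5, 50):
            vals = [geometric_tail_p(L, r) for r in (0.1, 0.2, 0.4, 0.8)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            geometric_tail_p(5, 0.0)
        with pytest.raises(ValueError):
            geometric_tail_p(5, 1.5)


class TestPoissonBaseline:
    def test_closed_forms(self):
        assert poisson_tail_p(0, 5.14) == 1.0
        assert poisson_tail_p(5.14, 5.14) == pytest.approx(math.exp(-1))

    def test_differs_from_geometric_at_saturating_density(self):
        """At rho = 0.195 the continuous approximation exp(-L*rho) visibly
        overstates the tail relative to the discrete (1-rho)^L."""
        rho = 0.195
        geo = geometric_tail_p(75, rho)
        poi = poisson_tail_p(75, 1 / rho)
        assert poi > geo
        assert poi / geo > 2  # a factor-level discrepancy, not rounding noise


class TestLongestRunDP:
    def test_edge_cases(self):
        assert longest_run_survival(10, 0.5, 0) == 1.0
        assert longest_run_survival(10, 0.5, 11) == 0.0
        assert longest_run_survival(3, 0.5, 3) == pytest.approx(0.125)

    def test_against_exhaustive_enumeration(self):
        """DP equals the exact probability from enumerating all 2^n occupancy
        strings weighted by their Bernoulli probabilities."""
        rho = 0.3
        n = 12
        for L in range(1, 6):
            total = 0.0
            for bits in range(2**n):
                occ = [(bits >> i) & 1 for i in range(n)]
                p = math.prod(rho if b else 1 - rho for b in occ)
                run = best = 0
                for b in occ:
                    run = 0 if b else run + 1
                    best = max(best, run)
                if best >= L:
                    total += p
            assert longest_run_survival(n, rho, L) == pytest.approx(total, abs=1e-12)


class TestGenomeNull:
    def test_saturated_genome_has_no_gaps(self):
        cfg = NullModelConfig(G=50, N=50, n_genome_instances=20, seed=1)
        res = simulate_genome_null(cfg)
        assert res.probability_at(1) == 0.0

    def test_pigeonhole_single_empty_site(self):
        cfg = NullModelConfig(G=10, N=9, n_genome_instances=50, seed=2)
        res = simulate_genome_null(cfg)
        assert res.probability_at(1) == 1.0
        assert res.probability_at(2) == 0.0

    def test_probability_column_monotone_and_bounded(self):
        cfg = NullModelConfig(G=5000, N=800, n_genome_instances=50, seed=3)
        res = simulate_genome_null(cfg)
        assert (np.diff(res.probability) <= 0).all()
        assert ((res.probability >= 0) & (res.probability <= 1)).all()
        assert (res.expected_count >= res.probability - 1e-12).all()

    def test_reproducible_from_seed(self):
        cfg = NullModelConfig(G=5000, N=800, n_genome_instances=20, seed=9)
        a, b = simulate_genome_null(cfg), simulate_genome_null(cfg)
        assert np.array_equal(a.probability, b.probability)
        assert np.array_equal(a.expected_count, b.expected_count)

    def test_invalid_N(self):
        with pytest.raises(ValueError):
            NullModelConfig(G=10, N=11)

    def test_circular_merges_end_gaps(self):
        # 2 sites in 10 bases: linear has 3 gaps, circular exactly 2
        cfg = NullModelConfig(G=10, N=2, n_genome_instances=200, seed=4)
        lin = simulate_genome_null(cfg, circular=False)
        circ = simulate_genome_null(cfg, circular=True)
        # total empty bases = 8 per instance in both; circular concentrates them
        assert circ.expected_count[0] <= lin.expected_count[0]


class TestGeneNull:
    def test_saturating_density_leaves_no_runs(self):
        cfg = NullModelConfig(G=100, N=100, g=50, n_gene_instances=500, seed=5)
        res = simulate_gene_null(cfg)
        assert res.probability_at(1) == 0.0

    def test_single_gap_probability(self):
        """g=3, rho=0.5: P(max run >= 3) = (1-rho)^3 = 0.125."""
        cfg = NullModelConfig(G=100, N=50, g=3, n_gene_instances=100_000, seed=6)
        res = simulate_gene_null(cfg)
        p = res.probability_at(3)
        se = math.sqrt(0.125 * 0.875 / 100_000)
        assert abs(p - 0.125) < 3 * se

    def test_full_curve_matches_dp_oracle(self):
        """Monte-Carlo survival curve agrees with the exact longest-run
        distribution at every L (the module's strongest oracle)."""
        cfg = NullModelConfig(
            G=1_000_000, N=300_000, g=60, n_gene_instances=50_000, seed=7
        )
        res = simulate_gene_null(cfg)
        L = np.arange(1, 31)
        exact = longest_run_survival_curve(cfg.g, cfg.rho, L)
        sim = np.array([res.probability_at(int(l)) for l in L])
        se = np.sqrt(exact * (1 - exact) / cfg.n_gene_instances)
        assert (np.abs(sim - exact) <= 3 * se + 1e-9).all()

    def test_gene_probability_below_genome_probability(self):
        """A 1-kb gene offers fewer IFR opportunities than a full genome at
        matched density."""
        G, N = 50_000, 9_750  # rho = 0.195
        gene = simulate_gene_null(
            NullModelConfig(G=G, N=N, g=1000, n_gene_instances=20_000, seed=8)
        )
        genome = simulate_genome_null(
            NullModelConfig(G=G, N=N, n_genome_instances=300, seed=8)
        )
        for L in (40, 60, 80):
            assert gene.probability_at(L) <= genome.probability_at(L) + 1e-9

    def test_reproducible_from_seed(self):
        cfg = NullModelConfig(G=1000, N=200, g=100, n_gene_instances=5000, seed=10)
        a, b = simulate_gene_null(cfg), simulate_gene_null(cfg)
        assert np.array_equal(a.probability, b.probability)


class TestCriticalLength:
    def _table(self, probs):
        cfg = NullModelConfig(G=100, N=50)
        L = np.arange(1, len(probs) + 1)
        return NullModelResult("gene", L, np.array(probs) + 0.1, np.array(probs), cfg)

    def test_step_table(self):
        res = self._table([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        assert critical_length(res, 0.5) == 5

    def test_alpha_below_table_minimum(self):
        res = self._table([1.0, 0.5, 0.2])
        with pytest.raises(TableRangeError):
            critical_length(res, 0.01)


class TestScanIFRs:
    def test_saturated_profile_yields_no_records(self):
        prof = InsertionProfile(np.ones(100, dtype=int), np.zeros(100, dtype=int))
        ann = GenomeAnnotation(100, [GeneRecord("g", 10, 60)])
        assert scan_ifrs(prof, ann) == []

    def test_boundaries_match_brute_force_scan(self):
        """Run boundaries agree with a naive scan on 1,000 random profiles;
        recomputing L from (start, end) is the identity."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            G = int(rng.integers(20, 200))
            occ = rng.random(G) < 0.3
            prof = InsertionProfile(occ.astype(int), np.zeros(G, dtype=int))
            runs = _maximal_zero_runs(prof.occupancy)
            expected = []
            start = None
            for i in range(G):
                if not occ[i] and start is None:
                    start = i
                if occ[i] and start is not None:
                    expected.append((start, i))
                    start = None
            if start is not None:
                expected.append((start, G))
            assert runs == expected
            for s, e in runs:
                assert e - s >= 1

    def test_gene_records_cover_max_intra_cds_run(self, gene_null_rho195):
        rng = np.random.default_rng(12)
        G = 5000
        occ = rng.random(G) < 0.195
        prof = InsertionProfile(occ.astype(int), np.zeros(G, dtype=int))
        ann = GenomeAnnotation(G, [GeneRecord("gA", 100, 1100)])
        records = scan_ifrs(prof, ann, null_gene=gene_null_rho195)
        gene_recs = [r for r in records if r.gene_id == "gA"]
        assert len(gene_recs) == 1
        r = gene_recs[0]
        from tradistat.gene_metrics import longest_zero_run

        assert r.L == longest_zero_run(prof.occupancy[100:1100])
        assert not math.isnan(r.p_gene)
        assert not math.isnan(r.p_gene_exact)
        # p_single <= p_gene: scanning a whole gene gives more opportunities
        assert r.p_single <= r.p_gene + 1e-12
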