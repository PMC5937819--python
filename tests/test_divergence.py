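import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from godiv import (
    OrthologMap,
    SimConfig,
    dgod,
    dgod_rate,
    fit_gamma_shape,
    neighborhood_status,
    pgod,
    simulate_pair,
    sliding_window_pgod,
)
from godiv.genome import Neighborhood

from conftest import brute_force_pgod, identity_map, make_genome


class TestNeighborhoodStatus:
    def test_adjacent_orthologs_are_conserved(self, five_gene_pair):
        a, b, m = five_gene_pair
        s = neighborhood_status(Neighborhood("a1", "a2", "chr1"), m, b)
        assert s.conserved and s.D_other == 1

    def test_missing_ortholog_is_lost_not_an_error(self, five_gene_pair):
        a, b, m = five_gene_pair
        m2 = OrthologMap([(f"a{i}", f"b{i}") for i in (1, 3, 4, 5)])
        s = neighborhood_status(Neighborhood("a1", "a2", "chr1"), m2, b)
        assert s.D_other is None and not s.conserved

    def test_threshold_widens_conservation(self):
        b = make_genome("B", {"chr1": ["b1", "b2", "b3", "b4"]})
        a = make_genome("A", {"chr1": ["a2", "a4"]})
        m = OrthologMap([("a2", "b2"), ("a4", "b4")])
        nb = Neighborhood("a2", "a4", "chr1")
        assert neighborhood_status(nb, m, b, threshold=1).D_other == 2
        assert not neighborhood_status(nb, m, b, threshold=1).conserved
        assert neighborhood_status(nb, m, b, threshold=2).conserved


class TestPgod:
    def test_identical_genomes_give_zero(self):
        a = make_genome("A", {"chr1": ["x", "y", "z"], "chr2": ["u", "v"]})
        b = make_genome("B", {"chr1": ["x", "y", "z"], "chr2": ["u", "v"]})
        assert pgod(a, b, identity_map(["x", "y", "z", "u", "v"])).pGOD == 0.0

    def test_worked_swap_example(self, five_gene_pair):
        a, b, m = five_gene_pair
        assert pgod(a, b, m).pGOD == pytest.approx(0.5)

    def test_no_shared_neighborhoods_gives_one(self):
        a = make_genome("A", {"chr1": ["a1", "a2", "a3", "a4"]})
        # odd/even orthologs split over two chromosomes: nothing stays adjacent
        b = make_genome("B", {"chr1": ["b1", "b3"], "chr2": ["b2", "b4"]})
        m = OrthologMap([(f"a{i}", f"b{i}") for i in range(1, 5)])
        assert pgod(a, b, m).pGOD == pytest.approx(1.0)

    def test_single_gene_chromosomes_are_an_error(self):
        a = make_genome("A", {"chr1": ["x"], "chr2": ["y"]})
        b = make_genome("B", {"chr1": ["x"], "chr2": ["y"]})
        with pytest.raises(ValueError, match="neighborhood"):
            pgod(a, b, identity_map(["x", "y"]))

    @pytest.mark.parametrize("seed", range(25))
    def test_symmetry_on_simulated_pairs(self, seed):
        cfg = SimConfig(n_genes=60, n_chromosomes=3, regional_shape=None, seed=seed,
                        events={"inversion": 2, "deletion": 2, "transposition": 1})
        a, b, truth = simulate_pair(cfg)
        ab = pgod(a, b, truth.ortholog_map).pGOD
        ba = pgod(b, a, truth.ortholog_map.reversed()).pGOD
        assert ab == ba

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle_on_small_genomes(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(
            n_genes=int(rng.integers(8, 21)), n_chromosomes=2, regional_shape=None,
            events={"inversion": int(rng.integers(0, 3)),
                    "deletion": int(rng.integers(0, 2)),
                    "tandem_duplication": int(rng.integers(0, 2))},
            seed=seed,
        )
        a, b, truth = simulate_pair(cfg)
        assert pgod(a, b, truth.ortholog_map).pGOD == pytest.approx(
            brute_force_pgod(a, b, truth.ortholog_map)
        )


class TestSlidingWindows:
    def test_identical_genomes_give_flat_zero_profile(self):
        ids = [f"g{i}" for i in range(100)]
        a = make_genome("A", {"chr1": ids})
        b = make_genome("B", {"chr1": ids})
        prof = sliding_window_pgod(a, b, identity_map(ids))
        assert len(prof) == 3
        assert np.all(prof.values == 0)

    def test_window_tiling_start_ranks(self):
        ids = [f"g{i}" for i in range(100)]
        a = make_genome("A", {"chr1": ids})
        b = make_genome("B", {"chr1": ids})
        prof = sliding_window_pgod(a, b, identity_map(ids), window=50, step=25)
        assert [w[1] for w in prof.windows] == [1, 26, 51]

    def test_single_loss_in_a_window(self):
        ids = [f"g{i}" for i in range(100)]
        a = make_genome("A", {"chr1": ids})
        # unmapped gene inserted between ranks 10 and 11 separates exactly
        # one neighborhood of A
        b = make_genome("B", {"chr1": ids[:10] + ["novel"] + ids[10:]})
        prof = sliding_window_pgod(a, b, identity_map(ids))
        assert prof.windows[0][2] == pytest.approx(1 / 49)
        assert prof.windows[1][2] == 0.0

    def test_small_genome_needs_smaller_window(self):
        ids = [f"g{i}" for i in range(20)]
        a = make_genome("A", {"chr1": ids})
        b = make_genome("B", {"chr1": ids})
        with pytest.raises(ValueError, match="smaller window"):
            sliding_window_pgod(a, b, identity_map(ids), window=50)


class TestGammaShape:
    def test_recovers_shape_of_gamma_samples(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(2.83, 0.05, size=10_000)
        assert fit_gamma_shape(x) == pytest.approx(2.83, abs=0.15)

    def test_constant_windows_are_unidentifiable(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gamma_shape(np.full(50, 0.2))

    def test_too_few_positive_windows(self):
        with pytest.raises(ValueError, match="positive windows"):
            fit_gamma_shape(np.array([0.0] * 30 + [0.1] * 5))

    def test_realistic_profile_shape_in_reported_range(self):
        # heterogeneity shape 2.8 over 800-gene blocks; fitted shape must
        # land inside the empirically reported 2.29-3.86 band
        window = 800
        cfg = SimConfig(n_genes=window * 300, n_chromosomes=4,
                        events={"inversion": int(0.06 * window * 300)},
                        regional_shape=2.8, regional_block=window, seed=7)
        a, b, truth = simulate_pair(cfg)
        prof = sliding_window_pgod(a, b, truth.ortholog_map, window, window)
        assert 2.29 <= fit_gamma_shape(prof) <= 3.86


class TestDgod:
    def test_zero_divergence_maps_to_zero(self):
        assert dgod(0.0, 2.83) == 0.0

    def test_reference_value(self):
        assert dgod(0.5, 2.83) == pytest.approx(0.78547, abs=1e-4)

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.6, 0.9])
    def test_poisson_limit(self, p):
        assert dgod(p, 1e6) == pytest.approx(-np.log(1 - p), rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="fully diverged"):
            dgod(1.0, 2.0)
        with pytest.raises(ValueError):
            dgod(-0.1, 2.0)
        with pytest.raises(ValueError):
            dgod(0.5, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.floats(min_value=1e-6, max_value=0.999),
        alpha=st.floats(min_value=0.05, max_value=500.0),
    )
    def test_gamma_correction_exceeds_poisson(self, p, alpha):
        assert dgod(p, alpha) >= -np.log(1 - p) - 1e-12

    def test_strictly_increasing_in_pgod(self):
        ps = np.linspace(0.0, 0.99, 200)
        for alpha in (0.5, 2.83, 50.0):
            d = [dgod(p, alpha) for p in ps]
            assert np.all(np.diff(d) > 0)


class TestDgodRate:
    def test_simple_division(self):
        assert dgod_rate(1.2, 0.3) == pytest.approx(4.0)

    @pytest.mark.parametrize("dist", [0.6, 0.61, 1.0])
    def test_saturated_pairs_excluded(self, dist):
        assert dgod_rate(1.0, dist) is None

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dgod_rate(1.0, 0.0)


def test_dgod_with_true_shape_grows_linearly_while_pgod_saturates():
    """Corrected distance tracks the applied event count almost linearly
    even where raw pGOD visibly saturates."""
    N = 5000
    events, pvals, dvals = [], [], []
    for E in range(0, 2 * N + 1, 500):
        cfg = SimConfig(n_genes=N, n_chromosomes=8, events={"inversion": E},
                        regional_shape=2.8, regional_block=50, seed=E + 5)
        a, b, truth = simulate_pair(cfg)
        p = pgod(a, b, truth.ortholog_map).pGOD
        events.append(E)
        pvals.append(p)
        dvals.append(dgod(p, 2.8))
    assert sps.spearmanr(events, dvals).statistic > 0.99
    assert sps.linregress(events, dvals).rvalue ** 2 > 0.98
    # raw pGOD increments shrink to less than half their initial size
    incr = np.diff(pvals)
    assert incr[-1] < 0.5 * incr[0]
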