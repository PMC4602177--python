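import numpy as np
import pytest

from conftest import make_state, simple_maps
from oracles import recursive_log_prior
from pdlrs.dlrs_dp import (
    compute_s_table,
    gene_tree_log_prior,
    simulation_consistency_check,
)
from pdlrs.gene_tree import GeneTreeState, GNode
from pdlrs.params import ModelParams, RateModel
from pdlrs.species_tree import discretize, parse_dated_species_tree
from pdlrs.two_type_bd import BDRates, compute_bd_tables


def theta_of(delta=0.4, mu=0.3, psi=0.4, mean=1.0, cv=0.6):
    return ModelParams(rates=BDRates(delta, mu, psi), rate_model=RateModel(mean, cv))


@pytest.fixture
def psi_state():
    species, classes = simple_maps(["a1", "b1", "b2"], pseudo=("b2",))
    return make_state("((b1:0.4,(b2:0.2)PSG:0.1):0.5,a1:0.9):0.6;", species, classes)


def single_leaf_state(length=0.8):
    root = GNode()
    root.add_child(GNode(length=length, name="a1"))
    return GeneTreeState(root, {"a1": "A"}, {"a1": "gene"})


class TestPrior:
    def test_single_species_no_events_is_length_density(self):
        """One species, all rates zero: the prior is just the relaxed-clock
        density of the single edge length over the stem-to-leaf time."""
        S = parse_dated_species_tree("(A:1.0):0.5;")
        Sp = discretize(S, n_points=4)
        theta = theta_of(0.0, 0.0, 0.0)
        st = single_leaf_state(0.8)
        lp = gene_tree_log_prior(st, theta, Sp)
        t_total = S.height
        expect = float(np.log(theta.rate_model.length_density(0.8, t_total)))
        assert lp == pytest.approx(expect, abs=1e-9)

    def test_support_restricted_to_sigma_subtree(self, psi_state, two_species_tree):
        Sp = discretize(two_species_tree, n_points=3)
        table = compute_s_table(psi_state, theta_of(), Sp)
        leaves = {l.name: l for l in psi_state.leaves()}
        b1 = leaves["b1"]
        # b1 maps to species leaf B: its diagonal is an indicator there
        b_pt = int(Sp.point_of_vertex[two_species_tree.name_to_leaf["B"]])
        vec = table.sdiag[b1]
        assert vec[b_pt] > 0
        assert vec.sum() == vec[b_pt]

    def test_matches_recursive_oracle_with_psi(self, psi_state, two_species_tree):
        Sp = discretize(two_species_tree, n_points=4)
        theta = theta_of()
        bd = compute_bd_tables(Sp, theta.rates)
        lp = gene_tree_log_prior(psi_state, theta, Sp, bd)
        lo = recursive_log_prior(psi_state, theta, Sp, bd)
        assert lp == pytest.approx(lo, abs=1e-8)

    def test_gene_only_reduction_random_instances(self, rng):
        """psi = 0, Psi empty: equals the independently coded recursion on
        random small instances."""
        S = parse_dated_species_tree("((A:1,B:1):1,C:2):0.5;")
        Sp = discretize(S, n_points=3)
        shapes = [
            ("((a1:{l1},b1:{l2}):{l3},c1:{l4}):{l5};", ["a1", "b1", "c1"]),
            ("((a1:{l1},a2:{l2}):{l3},b1:{l4}):{l5};", ["a1", "a2", "b1"]),
            ("(((a1:{l1},b1:{l2}):{l3},c1:{l4}):{l5},c2:{l6}):{l7};", ["a1", "b1", "c1", "c2"]),
        ]
        for i in range(6):
            tpl, names = shapes[i % len(shapes)]
            nwk = tpl.format(
                **{f"l{k}": round(float(rng.uniform(0.05, 1.5)), 4) for k in range(1, 8)}
            )
            species, classes = simple_maps(names)
            st = make_state(nwk, species, classes)
            theta = ModelParams(
                rates=BDRates(float(rng.uniform(0.1, 1.0)), float(rng.uniform(0.1, 1.0)), 0.0),
                rate_model=RateModel(float(rng.uniform(0.5, 1.5)), float(rng.uniform(0.3, 1.0))),
            )
            bd = compute_bd_tables(Sp, theta.rates)
            lp = gene_tree_log_prior(st, theta, Sp, bd)
            lo = recursive_log_prior(st, theta, Sp, bd)
            assert lp == pytest.approx(lo, abs=1e-8)

    def test_invariant_under_child_relabeling(self, two_species_tree):
        species, classes = simple_maps(["a1", "b1"])
        st1 = make_state("(a1:0.4,b1:0.7):0.5;", species, classes)
        st2 = make_state("(b1:0.7,a1:0.4):0.5;", species, classes)
        Sp = discretize(two_species_tree, n_points=4)
        theta = theta_of()
        assert gene_tree_log_prior(st1, theta, Sp) == pytest.approx(
            gene_tree_log_prior(st2, theta, Sp), rel=1e-12
        )

    def test_positive_density_for_valid_states(self, psi_state, two_species_tree):
        Sp = discretize(two_species_tree, n_points=4)
        lp = gene_tree_log_prior(psi_state, theta_of(), Sp)
        assert np.isfinite(lp)

    def test_zero_psi_rate_kills_psi_states(self, psi_state, two_species_tree):
        Sp = discretize(two_species_tree, n_points=4)
        lp = gene_tree_log_prior(psi_state, theta_of(psi=0.0), Sp)
        assert lp == -np.inf

    def test_refinement_stability(self, psi_state, two_species_tree):
        """Doubling the grid density changes the log prior by shrinking
        amounts (empirical Cauchy sequence)."""
        theta = theta_of()
        vals = []
        for n in (4, 16, 64, 256):
            Sp = discretize(two_species_tree, n_points=n)
            vals.append(gene_tree_log_prior(psi_state, theta, Sp))
        diffs = [abs(a - b) for a, b in zip(vals, vals[1:])]
        assert diffs[1] < diffs[0]
        assert diffs[2] < diffs[1]

    def test_psi_rate_shifts_mass_toward_psi_states(self, psi_state, two_species_tree):
        """Raising psi lowers the density of Psi-free states (their gene
        lineages must escape conversion) and favors Psi-carrying states
        relative to them."""
        Sp = discretize(two_species_tree, n_points=5)
        species, classes = simple_maps(["a1", "b1"])
        gene_state = make_state("(a1:0.4,b1:0.7):0.5;", species, classes)
        lp_gene = {
            p: gene_tree_log_prior(gene_state, theta_of(psi=p), Sp) for p in (0.2, 0.8)
        }
        lp_psi = {
            p: gene_tree_log_prior(psi_state, theta_of(psi=p), Sp) for p in (0.2, 0.8)
        }
        assert lp_gene[0.8] < lp_gene[0.2]
        assert lp_psi[0.8] - lp_psi[0.2] > lp_gene[0.8] - lp_gene[0.2]

    def test_length_density_integrates_to_topology_probability(self):
        """Integrating the single-leaf prior over the edge length recovers
        the lengths-marginalized DP value."""
        S = parse_dated_species_tree("(A:1.0):0.5;")
        Sp = discretize(S, n_points=4)
        theta = theta_of(0.3, 0.2, 0.0)
        grid = np.linspace(1e-6, 40.0, 8000)
        dens = []
        for l in grid:
            st = single_leaf_state(float(l))
            dens.append(np.exp(gene_tree_log_prior(st, theta, Sp)))
        integral = np.trapezoid(dens, grid)
        marg = np.exp(
            gene_tree_log_prior(single_leaf_state(1.0), theta, Sp, marginalize_lengths=True)
        )
        assert integral == pytest.approx(marg, rel=1e-3)


class TestSimulationConsistency:
    def test_no_event_rates_give_single_copy_certainty(self):
        S = parse_dated_species_tree("(A:1,B:1):0.5;")
        theta = theta_of(0.0, 0.0, 0.0)
        rep = simulation_consistency_check(theta, S, n_reps=200, seed=3)
        assert len(rep) == 1
        assert rep[0]["shape"] == "(A,B)"
        assert rep[0]["freq"] == 1.0
        assert rep[0]["dp_prob"] == pytest.approx(1.0, abs=1e-6)

    def test_frequent_shapes_match_dp(self):
        S = parse_dated_species_tree("(A:1,B:1):0.3;")
        theta = theta_of(0.4, 0.3, 0.4)
        Sp = discretize(S, n_points=40)
        rep = simulation_consistency_check(theta, S, n_reps=8000, seed=7, Sp=Sp, top_k=8)
        assert len(rep) >= 5
        for r in rep:
            assert abs(r["z"]) < 4.0

    def test_rank_correlation_of_shape_probabilities(self):
        from scipy.stats import spearmanr

        S = parse_dated_species_tree("(A:1,B:1):0.3;")
        theta = theta_of(0.4, 0.3, 0.4)
        Sp = discretize(S, n_points=25)
        rep = simulation_consistency_check(theta, S, n_reps=6000, seed=11, Sp=Sp, top_k=10)
        freqs = [r["freq"] for r in rep]
        probs = [r["dp_prob"] for r in rep]
        rho, _ = spearmanr(freqs, probs)
        assert rho > 0.8
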