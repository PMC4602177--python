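import numpy as np
import pytest

from conftest import make_state, simple_maps
from pdlrs.gene_tree import suppress, validate_state
from pdlrs.mcmc import (
    MCMCConfig,
    _nni_menu,
    _apply_nni,
    _nni_key,
    log_unnormalized_posterior,
    nj_initial_state,
    place_minimal_psi,
    propose_psi_slide,
    propose_scalar,
    run_chain,
    select_map_tree,
)
from pdlrs.params import ModelParams, RateModel
from pdlrs.pruning import CodonAlignment
from pdlrs.simulator import simulate_family
from pdlrs.species_tree import discretize, parse_dated_species_tree
from pdlrs.two_type_bd import BDRates


def theta_of(**kw):
    d = dict(delta=0.4, mu=0.4, psi=0.4, mean=1.0, cv=0.6, kappa=2.0, omega=0.5)
    d.update(kw)
    return ModelParams(
        rates=BDRates(d["delta"], d["mu"], d["psi"]),
        rate_model=RateModel(d["mean"], d["cv"]),
        kappa=d["kappa"],
        omega=d["omega"],
    )


@pytest.fixture(scope="module")
def family():
    S = parse_dated_species_tree("((A:0.5,B:0.5):0.5,C:1):0.1;")
    rng = np.random.default_rng(3)
    fam = simulate_family(S, theta_of(), omega=0.5, kappa=2.0, n_codons=60, rng=rng)
    return S, fam


class TestScalarProposals:
    def test_truncated_normal_stays_in_box_and_renormalizes(self, rng):
        from scipy.stats import kstest, truncnorm

        x, scale, lo, hi = 0.3, 1.0, 0.0, 2.0
        draws = np.array(
            [propose_scalar(rng, x, scale, lo, hi)[0] for _ in range(4000)]
        )
        assert draws.min() >= lo and draws.max() <= hi
        a, b = (lo - x) / scale, (hi - x) / scale
        stat, p = kstest(draws, truncnorm(a, b, loc=x, scale=scale).cdf)
        assert p > 1e-3

    def test_hastings_ratio_antisymmetric(self, rng):
        new, logh = propose_scalar(rng, 0.5, 0.3, 0.0, np.inf)
        # reverse correction is the negation by construction
        from pdlrs.mcmc import _truncnorm_logz

        expect = _truncnorm_logz(0.5, 0.3, 0.0, np.inf) - _truncnorm_logz(
            new, 0.3, 0.0, np.inf
        )
        assert logh == pytest.approx(expect)


class TestPsiSlide:
    @pytest.fixture
    def cherry_psi_state(self):
        species, classes = simple_maps(["p1", "p2", "g1"], pseudo=("p1", "p2"))
        return make_state(
            "(((p1:0.3,p2:0.3):0.2)PSG:0.2,g1:0.5):0.4;", species, classes
        )

    def test_down_then_up_round_trip(self, cherry_psi_state, rng):
        st = cherry_psi_state
        res = propose_psi_slide(st, rng)
        # direction is random; find a down move
        for _ in range(20):
            if res is not None and len(res[0].psi_vertices()) == 2:
                break
            res = propose_psi_slide(st, rng)
        down_state, _ = res
        assert validate_state(down_state) == []
        assert len(down_state.psi_vertices()) == 2
        for _ in range(40):
            res2 = propose_psi_slide(down_state, rng)
            if res2 is not None and len(res2[0].psi_vertices()) == 1:
                up_state, _ = res2
                break
        assert validate_state(up_state) == []
        # total lengths on the suppressed tree are preserved
        a = suppress(st).psi_edge_clades()
        b = suppress(up_state).psi_edge_clades()
        assert set(a) == set(b)
        for clade in a:
            assert sum(a[clade]) == pytest.approx(sum(b[clade]))

    def test_moves_preserve_validity(self, family, rng):
        S, fam = family
        st = fam.state
        for _ in range(50):
            res = propose_psi_slide(st, rng)
            if res is not None:
                assert validate_state(res[0]) == []


class TestTopologyMoves:
    def test_nni_results_valid_and_reversible(self, family):
        S, fam = family
        st = fam.state
        menu = _nni_menu(st)
        from pdlrs.dlrs_dp import shape_key

        for pair in menu:
            new = _apply_nni(st, _nni_key(st, pair))
            if new is None:
                continue
            assert validate_state(new) == []
            # the original shape is reachable back from the proposal
            back_shapes = set()
            for p2 in _nni_menu(new):
                b = _apply_nni(new, _nni_key(new, p2))
                if b is not None:
                    back_shapes.add(shape_key(b))
            assert shape_key(st) in back_shapes

    def test_nni_on_quartet_proposes_each_neighbor_once(self):
        species, classes = simple_maps(["a1", "b1", "c1", "d1"])
        st = make_state(
            "(((a1:1,b1:1):1,c1:2):1,d1:3):0.5;", species, classes
        )
        from pdlrs.dlrs_dp import shape_key

        shapes = set()
        counts = 0
        for pair in _nni_menu(st):
            new = _apply_nni(st, _nni_key(st, pair))
            if new is not None:
                shapes.add(shape_key(new))
                counts += 1
        # two internal edges, two swaps each
        assert counts == 4
        assert len(shapes) == 4


class TestPosterior:
    def test_identical_state_proposal_accepted_with_certainty(self, family):
        from pdlrs.mcmc import propose_identity

        S, fam = family
        Sp = discretize(S, n_points=3)
        D = CodonAlignment.from_sequences(fam.alignment)
        pi = np.full(64, 1 / 64)
        new, logh = propose_identity(fam.state)
        assert logh == 0.0
        t1, *_ = log_unnormalized_posterior(fam.state, theta_of(), D, Sp, pi)
        t2, *_ = log_unnormalized_posterior(new, theta_of(), D, Sp, pi)
        assert t2 == pytest.approx(t1, rel=1e-12)  # acceptance ratio 1

    def test_invalid_state_is_minus_inf(self, family):
        S, fam = family
        st = fam.state.copy()
        # strip one Psi so a pseudogene leaf is uncovered
        psi = st.psi_vertices()
        if psi:
            u = psi[0]
            (c,) = u.children
            p = u.parent
            c.length = float(c.length) + float(u.length)
            p.children[p.children.index(u)] = c
            c.parent = p
        Sp = discretize(S, n_points=3)
        D = CodonAlignment.from_sequences(fam.alignment)
        total, *_ = log_unnormalized_posterior(
            st, theta_of(), D, Sp, np.full(64, 1 / 64)
        )
        assert total == -np.inf

    def test_doubling_alignment_doubles_likelihood_term(self, family):
        S, fam = family
        Sp = discretize(S, n_points=3)
        D1 = CodonAlignment.from_sequences(fam.alignment)
        D2 = CodonAlignment.from_sequences(
            {k: v + v for k, v in fam.alignment.items()}
        )
        pi = np.full(64, 1 / 64)
        _, ll1, lt1, lth1, _ = log_unnormalized_posterior(fam.state, theta_of(), D1, Sp, pi)
        _, ll2, lt2, lth2, _ = log_unnormalized_posterior(fam.state, theta_of(), D2, Sp, pi)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)
        assert lt2 == lt1 and lth2 == lth1


class TestChain:
    def test_same_seed_identical_trace(self, family):
        S, fam = family
        D = CodonAlignment.from_sequences(fam.alignment)
        cfg = MCMCConfig(iterations=300, burn_in=100, thinning=10, seed=42)
        t1 = run_chain(D, S, cfg, leaf_species=fam.state.leaf_species,
                       leaf_class=fam.state.leaf_class)
        t2 = run_chain(D, S, cfg, leaf_species=fam.state.leaf_species,
                       leaf_class=fam.state.leaf_class)
        assert t1.scalars().equals(t2.scalars())
        assert [r.newick for r in t1.records] == [r.newick for r in t2.records]

    def test_fixed_tree_mode_disables_topology_moves(self, family):
        S, fam = family
        D = CodonAlignment.from_sequences(fam.alignment)
        cfg = MCMCConfig(iterations=300, burn_in=100, thinning=10, seed=1, fixed_tree=True)
        tr = run_chain(D, S, cfg, initial_state=fam.state)
        for move in ("nni", "spr", "reroot"):
            assert tr.acceptance[move] == (0, 0)
        # topology unchanged in every sample
        from pdlrs.distances import gstar_clades

        for r in tr.records:
            assert gstar_clades(r.state) == gstar_clades(fam.state)

    def test_nj_initial_state_valid(self, family):
        S, fam = family
        D = CodonAlignment.from_sequences(fam.alignment)
        st = nj_initial_state(D, fam.state.leaf_species, fam.state.leaf_class)
        assert validate_state(st) == []
        assert sorted(l.name for l in st.leaves()) == sorted(fam.alignment)

    def test_minimal_psi_placement_is_minimal_and_valid(self):
        species, classes = simple_maps(
            ["p1", "p2", "g1", "q1"], pseudo=("p1", "p2", "q1")
        )
        st = make_state(
            "(((p1:0.4,p2:0.4):0.2,g1:0.6):0.3,q1:0.9):0.5;", species, classes
        )
        for n in st.root.postorder():  # strip classes-only tree of psi
            assert not n.is_psi
        placed = place_minimal_psi(st)
        assert validate_state(placed) == []
        clades = {
            frozenset(l.name for l in u.leaves()) for u in placed.psi_vertices()
        }
        assert clades == {frozenset({"p1", "p2"}), frozenset({"q1"})}


class TestSelectMapTree:
    def _trace_with(self, lp, family):
        from pdlrs.mcmc import PosteriorTrace, TraceRecord

        S, fam = family
        rec = TraceRecord(
            iteration=1, log_posterior=lp, log_likelihood=0, log_tree_prior=0,
            log_theta_prior=0, delta=0, mu=0, psi=0, rate_mean=1, rate_cv=1,
            kappa=1, omega=1, n_psi=0, newick="", state=fam.state,
        )
        return PosteriorTrace(records=[rec], acceptance={}, config=MCMCConfig())

    def test_single_candidate_and_highest_wins(self, family):
        t1 = self._trace_with(-10.0, family)
        t2 = self._trace_with(-5.0, family)
        assert select_map_tree([t1])[0] == 0
        assert select_map_tree([t1, t2])[0] == 1

    def test_tie_keeps_first_seen(self, family):
        t1 = self._trace_with(-7.0, family)
        t2 = self._trace_with(-7.0, family)
        assert select_map_tree([t1, t2])[0] == 0
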