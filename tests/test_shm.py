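"""Unit and property tests for the somatic-hypermutation engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gcsim import GCState, ModelParams, ParameterError
from gcsim.params import LEAF_NAMES, AffinityChangeParams, MutationTreeParams
from gcsim.shm import (
    apply_shm_step,
    classify_mutation,
    daughter_leave_probability,
    decide_cell_fate,
    draw_affinity_delta,
    draw_mutation_count,
)


class ScriptedRng:
    """Deterministic stand-in for a Generator, replaying scripted draws."""

    def __init__(self, poisson=None, multinomial=None, gamma=None, uniform=None):
        self._poisson = list(poisson or [])
        self._multinomial = list(multinomial or [])
        self._gamma = list(gamma or [])
        self._uniform = list(uniform or [])

    def poisson(self, lam, size=None):
        out = self._poisson.pop(0)
        return np.asarray(out) if size is not None else out

    def multinomial(self, n, pvals):
        return np.asarray(self._multinomial.pop(0))

    def gamma(self, shape, scale, size=None):
        out = self._gamma.pop(0)
        return np.asarray(out) if size is not None else out

    def random(self):
        return self._uniform.pop(0)


class TestMutationCount:
    def test_mean_matches_rate(self, rng):
        draws = rng.poisson(0.6, 100_000)  # reference
        ours = np.array([draw_mutation_count(rng, 0.6) for _ in range(20_000)])
        assert abs(ours.mean() - 0.6) < 0.02
        assert abs(draws.mean() - 0.6) < 0.01

    def test_zero_rate_is_degenerate(self, rng):
        assert all(draw_mutation_count(rng, 0.0) == 0 for _ in range(100))

    def test_probability_of_no_mutation(self, rng):
        n = 100_000
        zeros = sum(draw_mutation_count(rng, 0.6) == 0 for _ in range(n)) / n
        assert abs(zeros - math.exp(-0.6)) < 0.006  # ~4 SE

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ParameterError):
            draw_mutation_count(rng, -0.1)


class TestClassifyMutation:
    def test_forced_lethal_path(self, rng):
        tree = MutationTreeParams(p_fwr=1, p_repl_fwr=1, p_lethal_fwr=1)
        for _ in range(50):
            assert classify_mutation(rng, tree).category == "fwr_replacement_lethal"

    def test_forced_silent_path(self, rng):
        tree = MutationTreeParams(p_fwr=0, p_repl_cdr=0)
        for _ in range(50):
            assert classify_mutation(rng, tree).category == "silent"

    @settings(max_examples=15, deadline=None)
    @given(
        p_fwr=st.floats(0.05, 0.95),
        p_rf=st.floats(0.05, 0.95),
        p_rc=st.floats(0.05, 0.95),
        p_l=st.floats(0.05, 0.95),
        p_a=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**20),
    )
    def test_leaf_frequencies_match_branch_products(self, p_fwr, p_rf, p_rc, p_l, p_a, seed):
        """Empirical leaf frequencies converge to products of branch
        probabilities (within 4 standard errors) for arbitrary valid trees."""
        tree = MutationTreeParams(p_fwr, p_rf, p_rc, p_l, p_a)
        expected = tree.leaf_probabilities()
        assert expected.sum() == pytest.approx(1.0)
        gen = np.random.default_rng(seed)
        n = 20_000
        counts = dict.fromkeys(LEAF_NAMES, 0)
        for _ in range(n):
            counts[classify_mutation(gen, tree).category] += 1
        for leaf, p in zip(LEAF_NAMES, expected):
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(counts[leaf] / n - p) <= 4 * se + 1e-9


class TestAffinityDelta:
    @pytest.mark.parametrize("sigma_parent", [0.0, 1.0, 5.0])
    def test_mean_is_minus_shift_times_parent(self, rng, sigma_parent):
        params = AffinityChangeParams()
        draws = np.array([draw_affinity_delta(rng, sigma_parent, params)
                          for _ in range(60_000)])
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - (-0.1 * sigma_parent)) < 5 * se

    def test_mean_decreases_with_parent_affinity(self, rng):
        params = AffinityChangeParams()
        means = []
        for sp in (0.0, 1.0, 5.0):
            d = [draw_affinity_delta(rng, sp, params) for _ in range(20_000)]
            means.append(np.mean(d))
        assert means[0] > means[1] > means[2]

    def test_right_skew(self, rng):
        params = AffinityChangeParams()
        d = np.array([draw_affinity_delta(rng, 0.0, params) for _ in range(50_000)])
        assert stats.skew(d) > 0

    def test_matches_scipy_invgamma(self, rng):
        """The sampled base distribution agrees with scipy's inverse gamma
        (independent parameterization check via a KS test)."""
        params = AffinityChangeParams()
        d = np.array([draw_affinity_delta(rng, 0.0, params) for _ in range(5_000)])
        x = d + params.mean  # recover raw inverse-gamma variates
        ks = stats.kstest(x, stats.invgamma(a=3, scale=0.3).cdf)
        assert ks.pvalue > 1e-3
        assert params.mean == pytest.approx(0.3 / (3 - 1))

    def test_shape_at_most_two_rejected(self):
        with pytest.raises(ParameterError):
            AffinityChangeParams(shape=2.0)


class TestCellFate:
    TREE = MutationTreeParams()
    AFF = AffinityChangeParams()

    def test_no_mutations_unchanged(self, rng):
        fate = decide_cell_fate(rng, 0, self.TREE, self.AFF, 1.0)
        assert fate.disposition == "unchanged"
        assert fate.total_delta_affinity == 0.0

    def test_any_lethal_kills(self, rng):
        tree = MutationTreeParams(p_fwr=1, p_repl_fwr=1, p_lethal_fwr=1)
        fate = decide_cell_fate(rng, 2, tree, self.AFF, 1.0)
        assert fate.disposition == "dies"

    def test_silent_mutation_level_rule(self, rng):
        tree = MutationTreeParams(p_fwr=0, p_repl_cdr=0)  # always silent
        pep = decide_cell_fate(rng, 1, tree, self.AFF, 1.0, level="peptide")
        nt = decide_cell_fate(rng, 1, tree, self.AFF, 1.0, level="nucleotide")
        assert pep.disposition == "unchanged"
        assert nt.disposition == "spawns_new_subclone"
        assert nt.total_delta_affinity == 0.0

    def test_affinity_only_peptide_rule(self, rng):
        neutral_tree = MutationTreeParams(p_fwr=0, p_repl_cdr=1, p_affinity_cdr=0)
        fate = decide_cell_fate(rng, 1, neutral_tree, self.AFF, 1.0,
                                level="peptide", peptide_spawn_rule="affinity_only")
        assert fate.disposition == "unchanged"
        fate = decide_cell_fate(rng, 1, neutral_tree, self.AFF, 1.0,
                                level="peptide")
        assert fate.disposition == "spawns_new_subclone"

    def test_single_delta_for_multiple_affinity_hits(self, rng):
        tree = MutationTreeParams(p_fwr=0, p_repl_cdr=1, p_affinity_cdr=1)
        fate = decide_cell_fate(rng, 3, tree, self.AFF, 1.0)
        nonzero = [o.delta_affinity for o in fate.outcomes if o.delta_affinity != 0.0]
        assert len(nonzero) <= 1
        assert fate.total_delta_affinity == pytest.approx(sum(nonzero))


def _one_clone_state(cb, sigma=1.0):
    state = GCState()
    state.add_subclones(sigma=sigma, n_mutations=0,
                        parent_ids=GCState.NO_PARENT, cb=cb)
    return state


class TestApplyShmStep:
    def test_subunit_clone_untouched(self, rng):
        state = _one_clone_state(0.7)
        rec = apply_shm_step(state, rng, ModelParams())
        assert rec.n_spawned == 0 and rec.n_lethal == 0
        assert state.cb[0] == 0.7

    def test_no_mutations_leaves_state_unchanged(self):
        state = _one_clone_state(3.0)
        stub = ScriptedRng(poisson=[[0, 0, 0]])
        rec = apply_shm_step(state, stub, ModelParams())
        assert rec.n_spawned == 0 and state.cb[0] == 3.0

    def test_scripted_fates_update_parent_and_child(self):
        """Three daughters: unchanged / lethal / affinity spawn (+0.5)."""
        sigma_parent = 1.0
        params = ModelParams()
        state = _one_clone_state(3.0, sigma=sigma_parent)
        x = 0.5 + params.affinity.mean + 0.1 * sigma_parent  # raw invgamma draw
        stub = ScriptedRng(
            poisson=[[0, 1, 1]],
            multinomial=[[[0, 1, 0, 0, 0], [0, 0, 0, 0, 1]]],
            gamma=[[1.0 / x]],
        )
        rec = apply_shm_step(state, stub, params)
        assert rec.n_lethal == 1 and rec.n_spawned == 1
        assert state.cb[0] == pytest.approx(1.0)   # 3 - 1 dead - 1 spawned
        assert state.cb[1] == 1.0
        assert state.sigma[1] == pytest.approx(sigma_parent + 0.5)
        assert state.n_mutations[1] == 1

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**20),
           cb=st.lists(st.floats(0.2, 30.0), min_size=1, max_size=8))
    def test_cb_conservation_up_to_lethal_deaths(self, seed, cb):
        """Sum of CB changes only by the number of lethal deaths: every
        spawned CB=1 is offset by a parent decrement of 1."""
        state = GCState()
        state.add_subclones(sigma=np.linspace(0.5, 2.0, len(cb)),
                            n_mutations=0, parent_ids=GCState.NO_PARENT, cb=cb)
        before = state.cb.sum()
        rec = apply_shm_step(state, np.random.default_rng(seed), ModelParams())
        assert state.cb.sum() == pytest.approx(before - rec.n_lethal)
        assert (state.cb >= 0).all()

    def test_affinity_floor_clamps_children(self):
        params = ModelParams()
        state = _one_clone_state(2.0, sigma=0.01)
        stub = ScriptedRng(
            poisson=[[1, 0]],
            multinomial=[[[0, 0, 0, 0, 1]]],
            gamma=[[1.0 / 1e-9]],  # near-zero invgamma draw: large negative delta
        )
        apply_shm_step(state, stub, params)
        assert state.sigma[1] == params.affinity.min_affinity

    def test_mutation_counts_accumulate_along_lineage(self, rng):
        """A child's recorded mutation count equals its parent's plus its own m."""
        params = ModelParams()
        state = _one_clone_state(50.0)
        for _ in range(6):
            state.cb = np.maximum(state.cb, 1.0)  # keep everyone eligible
            apply_shm_step(state, rng, params)
        events_m = dict(zip(state.ids.tolist(), state.n_mutations.tolist()))
        parents = dict(zip(state.ids.tolist(), state.parent_ids.tolist()))
        for cid, pid in parents.items():
            if pid >= 0 and pid in events_m:
                assert events_m[cid] > events_m[pid] >= 0

    def test_per_subclone_mode_single_daughter(self):
        state = _one_clone_state(40.0)
        params = ModelParams(shm_sampling="per_subclone")
        stub = ScriptedRng(poisson=[[1]], multinomial=[[[1, 0, 0, 0, 0]]])
        rec = apply_shm_step(state, stub, params)
        assert rec.n_spawned == 1  # one daughter, not forty

    def test_subunit_loss_mode_taxes_small_clones(self, rng):
        params = ModelParams(subunit_mutation_loss=True)
        state = _one_clone_state(0.5)
        apply_shm_step(state, rng, params)
        expected = 0.5 * (1 - daughter_leave_probability(params))
        assert state.cb[0] == pytest.approx(expected)


def test_daughter_leave_probability_levels():
    nt = daughter_leave_probability(ModelParams(subclone_level="nucleotide"))
    pep = daughter_leave_probability(ModelParams(subclone_level="peptide"))
    strict = daughter_leave_probability(
        ModelParams(subclone_level="peptide", peptide_spawn_rule="affinity_only"))
    assert nt == pytest.approx(1 - math.exp(-0.6))
    assert 0 < strict < pep < nt
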