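"""SSE likelihood: tip conditions, branch ODEs, pruning, and reconstruction.

Oracles: dense matrix exponentials for the pure character-evolution (Mk)
limit, the closed-form Yule likelihood for the single-state pure-birth case,
and the adaptive per-branch integrator as an independent route through the
same model.
"""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from hypersse.likelihood import (AnnotatedTree, RootSpec, SamplingFractions,
                                 combine_node, integrate_branch, loglik,
                                 marginal_asr, mk_loglik_expm, tip_initialize)
from hypersse.trait_space import (Bipartition, DIVERSIFICATION_MODELS,
                                  RateModelSpec, RateSet, StateSpace,
                                  TRANSITION_MODELS, build_rateset)


def mk_rateset(space, q_params, rng=None):
    """lambda = mu = 0, random or given transition rates on hypercube edges."""
    spec = RateModelSpec(TRANSITION_MODELS["free"],
                         DIVERSIFICATION_MODELS["all-equal"])
    return build_rateset(Bipartition("0" + "*" * (space.n_chars - 1)), spec,
                         np.concatenate([[0.0, 0.0], q_params]), space)


def random_annotated(tree_factory, rng, n_tips, space, depth_scale=10.0):
    tree = tree_factory(n_tips, rng, depth_scale)
    states = {f"t{i}": int(rng.integers(space.n_states))
              for i in range(n_tips)}
    return AnnotatedTree(tree, states)


class TestTipInitialize:
    def test_uniform_sampling_fraction(self):
        f = 464 / 250_000
        sampling = SamplingFractions.uniform(f, 64)
        D, E = tip_initialize(5, sampling)
        assert D[5] == pytest.approx(0.001856)
        assert np.count_nonzero(D) == 1
        assert np.allclose(E, 0.998144)

    def test_complete_sampling(self):
        sampling = SamplingFractions.uniform(1.0, 4)
        D, E = tip_initialize(2, sampling)
        assert D.tolist() == [0, 0, 1, 0]
        assert not E.any()

    def test_missing_state(self):
        sampling = SamplingFractions.uniform(1.0, 4)
        D, E = tip_initialize(None, sampling)
        assert D.tolist() == [1, 1, 1, 1]
        assert not E.any()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SamplingFractions.uniform(0.0, 4)
        with pytest.raises(ValueError):
            SamplingFractions.uniform(1.5, 4)


class TestIntegrateBranch:
    def test_zero_duration_identity(self, rng):
        space = StateSpace(2)
        rs = mk_rateset(space, rng.uniform(0.01, 0.2, 4))
        D0 = rng.uniform(0, 1, 4)
        E0 = rng.uniform(0, 0.5, 4)
        D, E = integrate_branch(D0, E0, rs, 0.0)
        assert np.array_equal(D, D0) and np.array_equal(E, E0)

    def test_mk_limit_matches_expm(self, rng):
        """With lambda = mu = 0 the D update is the matrix-exponential action."""
        space = StateSpace(2)
        for _ in range(5):
            rs = mk_rateset(space, rng.uniform(0.01, 0.3, 4))
            D0 = rng.uniform(0, 1, 4)
            t = rng.uniform(0.5, 5.0)
            D, E = integrate_branch(D0, np.zeros(4), rs, t)
            assert np.allclose(D, expm(rs.Q * t) @ D0, atol=1e-8)
            assert np.allclose(E, 0.0, atol=1e-10)

    def test_yule_closed_form_decay(self):
        """Single state, mu = 0, E = 0: D(t) = D(0) exp(-lambda t)."""
        lam = 0.17
        rs = RateSet(np.array([lam]), np.zeros(1), np.zeros((1, 1)))
        D, E = integrate_branch(np.array([0.8]), np.array([0.0]), rs, 7.0)
        assert D[0] == pytest.approx(0.8 * math.exp(-lam * 7.0), rel=1e-7)
        assert E[0] == pytest.approx(0.0, abs=1e-10)

    def test_E_monotone_from_zero(self):
        """E grows monotonically from 0 and stays below 1."""
        space = StateSpace(1)
        rs = RateSet(np.array([0.1, 0.1]), np.array([0.05, 0.02]),
                     np.array([[-0.01, 0.01], [0.03, -0.03]]))
        E = np.zeros(2)
        D = np.ones(2)
        prev = E.copy()
        for _ in range(30):
            D, E = integrate_branch(D, E, rs, 2.0)
            assert (E >= prev - 1e-12).all() and (E <= 1.0).all()
            prev = E.copy()

    def test_negative_duration_rejected(self):
        rs = RateSet(np.zeros(1), np.zeros(1), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            integrate_branch(np.ones(1), np.zeros(1), rs, -1.0)


class TestCombineNode:
    def test_identity_under_unit_rates(self):
        rs = RateSet(np.ones(3), np.zeros(3), np.zeros((3, 3)))
        assert combine_node(np.ones(3), np.ones(3), rs).tolist() == [1, 1, 1]

    def test_zero_propagates(self):
        rs = RateSet(np.full(3, 0.2), np.zeros(3), np.zeros((3, 3)))
        out = combine_node(np.array([0.0, 1, 1]), np.array([0.0, 1, 0]), rs)
        assert out[0] == 0 and out[2] == 0


class TestLoglik:
    def test_probability_one_case(self, tree_factory, rng):
        """Zero rates, complete sampling, all tips in the fixed root state."""
        space = StateSpace(2)
        tree = tree_factory(6, rng)
        atree = AnnotatedTree(tree, {f"t{i}": 0 for i in range(6)})
        rs = RateSet(np.zeros(4), np.zeros(4), np.zeros((4, 4)))
        ll = loglik(atree, rs, SamplingFractions.uniform(1.0, 4),
                    RootSpec.fixed(0, 4))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_incompatible_fixed_root_is_minus_inf(self, tree_factory, rng):
        space = StateSpace(1)
        tree = tree_factory(4, rng)
        atree = AnnotatedTree(tree, {f"t{i}": 0 for i in range(4)})
        rs = RateSet(np.zeros(2), np.zeros(2), np.zeros((2, 2)))
        ll = loglik(atree, rs, SamplingFractions.uniform(1.0, 2),
                    RootSpec.fixed(1, 2))
        assert ll == -math.inf

    def test_mk_agreement_random_trees(self, tree_factory, rng):
        """lambda = mu = 0 equals the matrix-exponential Mk oracle."""
        space = StateSpace(2)
        for _ in range(10):
            atree = random_annotated(tree_factory, rng, 8, space)
            rs = mk_rateset(space, rng.uniform(0.02, 0.3, 4))
            root = RootSpec.given(np.full(4, 0.25))
            ll = loglik(atree, rs, SamplingFractions.uniform(1.0, 4), root,
                        max_step=0.05)
            oracle = mk_loglik_expm(atree, rs.Q, root.weights)
            assert ll == pytest.approx(oracle, abs=1e-6)

    def test_yule_closed_form(self, tree_factory, rng):
        """Single state, pure birth: L = lambda^(n-1) exp(-lambda * treelen)."""
        lam = 0.13
        tree = tree_factory(5, rng)
        atree = AnnotatedTree(tree, {f"t{i}": 0 for i in range(5)})
        rs = RateSet(np.array([lam]), np.zeros(1), np.zeros((1, 1)))
        ll = loglik(atree, rs, SamplingFractions.uniform(1.0, 1),
                    RootSpec.fixed(0, 1), max_step=0.05)
        tree.calc_node_root_distances()
        tree_len = sum(e.length for e in tree.preorder_edge_iter()
                       if e.length is not None)
        assert ll == pytest.approx(4 * math.log(lam) - lam * tree_len,
                                   rel=1e-7)

    def test_methods_agree(self, tree_factory, rng):
        """Fast synchronous sweep vs independent per-branch adaptive solver."""
        space = StateSpace(2)
        spec = RateModelSpec(TRANSITION_MODELS["free"],
                             DIVERSIFICATION_MODELS["free"])
        for _ in range(4):
            atree = random_annotated(tree_factory, rng, 4, space)
            params = np.concatenate([rng.uniform(0.02, 0.15, 2),
                                     rng.uniform(0.0, 0.03, 2),
                                     rng.uniform(0.005, 0.1, 4)])
            rs = build_rateset(Bipartition("0*"), spec, params, space)
            sampling = SamplingFractions.uniform(0.6, 4)
            root = RootSpec.fixed(0, 4)
            fast = loglik(atree, rs, sampling, root, max_step=0.02)
            ref = loglik(atree, rs, sampling, root, method="per-branch")
            assert fast == pytest.approx(ref, abs=1e-5)

    def test_invariant_to_child_rotation(self, tree_factory, rng):
        space = StateSpace(2)
        atree = random_annotated(tree_factory, rng, 8, space)
        spec = RateModelSpec(TRANSITION_MODELS["one-rate"],
                             DIVERSIFICATION_MODELS["free"])
        rs = build_rateset(Bipartition("0*"), spec,
                           [0.08, 0.05, 0.01, 0.005, 0.02], space)
        sampling = SamplingFractions.uniform(0.8, 4)
        root = RootSpec.fixed(0, 4)
        before = loglik(atree, rs, sampling, root)
        for nd in atree.tree.preorder_node_iter():
            ch = nd.child_nodes()
            if len(ch) == 2:
                nd.set_child_nodes([ch[1], ch[0]])
        rotated = AnnotatedTree(atree.tree, atree.tip_states)
        assert loglik(rotated, rs, sampling, root) == pytest.approx(
            before, abs=1e-9)

    def test_non_ultrametric_rejected(self, tree_factory, rng):
        tree = tree_factory(4, rng)
        for lf in tree.leaf_node_iter():
            lf.edge.length += 1.0
            break
        atree = AnnotatedTree(tree, {f"t{i}": 0 for i in range(4)})
        rs = RateSet(np.zeros(2), np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            loglik(atree, rs, SamplingFractions.uniform(1.0, 2),
                   RootSpec.fixed(0, 2))

    def test_conditioning_changes_likelihood(self, tree_factory, rng):
        space = StateSpace(1)
        tree = tree_factory(5, rng)
        atree = AnnotatedTree(tree, {f"t{i}": 0 for i in range(5)})
        rs = RateSet(np.array([0.1]), np.array([0.03]), np.zeros((1, 1)))
        sampling = SamplingFractions.uniform(0.8, 1)
        root = RootSpec.fixed(0, 1)
        plain = loglik(atree, rs, sampling, root)
        cond = loglik(atree, rs, sampling, root, condition_on_survival=True)
        assert np.isfinite(plain) and np.isfinite(cond)
        assert cond > plain  # dividing by a probability < 1


class TestMarginalASR:
    def test_fixed_root_is_certain(self, tree_factory, rng):
        space = StateSpace(2)
        atree = random_annotated(tree_factory, rng, 6, space)
        rs = mk_rateset(space, np.full(4, 0.05))
        probs = marginal_asr(atree, rs, SamplingFractions.uniform(1.0, 4),
                             RootSpec.fixed(0, 4))
        assert probs["root"][0] == pytest.approx(1.0)

    def test_matches_clamped_mk_oracle(self, tree_factory, rng):
        """Marginal probabilities equal renormalised clamped-node likelihoods
        computed with an independent matrix-exponential recursion."""
        space = StateSpace(2)
        atree = random_annotated(tree_factory, rng, 8, space)
        rs = mk_rateset(space, rng.uniform(0.03, 0.2, 4))
        root = RootSpec.given(np.full(4, 0.25))
        probs = marginal_asr(atree, rs, SamplingFractions.uniform(1.0, 4), root)

        arr = atree.arrays()

        def clamped_ll(node_clamp, state):
            logsc, D = 0.0, {}
            for node in arr.order:
                if arr.is_tip[node]:
                    D[node] = np.eye(4)[atree.tip_states[arr.tip_label[node]]]
                else:
                    cl, cr = arr.children[node]
                    Pl = expm(rs.Q * (arr.height[node] - arr.height[cl]))
                    Pr = expm(rs.Q * (arr.height[node] - arr.height[cr]))
                    v = (Pl @ D[cl]) * (Pr @ D[cr])
                    if node == node_clamp:
                        keep = v[state]
                        v = np.zeros(4)
                        v[state] = keep
                    if v.max() <= 0:
                        return -math.inf
                    logsc += math.log(v.max())
                    D[node] = v / v.max()
            mass = root.weights @ D[arr.root]
            return math.log(mass) + logsc if mass > 0 else -math.inf

        for node in range(arr.n_nodes):
            if arr.is_tip[node]:
                continue
            lls = np.array([clamped_ll(node, s) for s in range(4)])
            ref = np.exp(lls - lls.max())
            ref /= ref.sum()
            assert np.allclose(probs[node], ref, atol=1e-7)

    def test_uniform_tips_tiny_q_concentrate(self, tree_factory, rng):
        space = StateSpace(2)
        tree = tree_factory(6, rng)
        atree = AnnotatedTree(tree, {f"t{i}": 3 for i in range(6)})
        rs = mk_rateset(space, np.full(4, 1e-5))
        probs = marginal_asr(atree, rs, SamplingFractions.uniform(1.0, 4),
                             RootSpec.given(np.full(4, 0.25)))
        for key, p in probs.items():
            if key == "root":
                continue
            assert p[3] > 0.99

    def test_tips_concentrate_on_observed(self, tree_factory, rng):
        space = StateSpace(2)
        atree = random_annotated(tree_factory, rng, 5, space)
        rs = mk_rateset(space, np.full(4, 0.05))
        probs = marginal_asr(atree, rs, SamplingFractions.uniform(1.0, 4),
                             RootSpec.given(np.full(4, 0.25)))
        for lab, s in atree.tip_states.items():
            assert probs[lab][s] == pytest.approx(1.0)
            assert all(abs(v.sum() - 1) < 1e-9 for v in probs.values())
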