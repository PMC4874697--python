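"""Multistate SSE (MuSSE) likelihood on a time-calibrated tree.

The model: each lineage carries one of ``n`` states; a lineage in state ``i``
speciates at rate ``lambda_i``, goes extinct at rate ``mu_i``, and changes to
state ``j`` at rate ``q_ij`` (non-zero only between hypercube neighbours).
The probability of the observed tip data is computed by the standard pruning
construction with two coupled quantities per state,

    E_i(t)  - probability that a lineage alive in state i at time t before the
              present leaves no sampled descendant,
    D_i(t)  - probability density of the observed subtree descending from a
              lineage in state i at time t,

which obey

    dE_i/dt = mu_i - (lambda_i + mu_i + sum_j q_ij) E_i
              + lambda_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + sum_j q_ij) D_i
              + 2 lambda_i E_i D_i + sum_j q_ij D_j

with tip conditions D_i = f_i (sampled state) and E_i = 1 - f_i for per-state
sampling fractions f.  At an internal node, D_i = lambda_i * D_left,i *
D_right,i.  The root is handled either with a fixed state (the default here:
lineages begin with the all-ancestral combination) or a weight vector.

Two integration back ends are provided:

``method="fast"`` (default)
    A single synchronous sweep from the present to the root.  Because the
    tree is ultrametric and all tips share one sampling-fraction vector, the
    E trajectory is identical on every branch; it is integrated once,
    jointly with the D vectors of all branches alive in the current time
    slice, using fixed-step classical Runge-Kutta (step bounded by
    ``max_step``).  The D equation is linear given E, so the sweep advances
    an (n_states x n_active) matrix with one small matrix product per stage.

``method="per-branch"``
    Textbook post-order recursion integrating the joint nonlinear (D, E)
    system on each branch with ``scipy.integrate.solve_ivp``.  Slower, but
    it makes no shared-E assumption and serves as an independent
    cross-check of the fast sweep.

Underflow is controlled by renormalising D at every node (and periodically
along the sweep) while accumulating the logarithm of the removed factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .trait_space import RateSet, StateSpace

__all__ = [
    "SamplingFractions",
    "RootSpec",
    "AnnotatedTree",
    "tip_initialize",
    "integrate_branch",
    "combine_node",
    "loglik",
    "marginal_asr",
]

#: default ODE tolerances for the per-branch integrator
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10
#: default maximum step (Myr) of the fixed-step sweep
SWEEP_MAX_STEP = 0.25
#: relative tolerance for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Input containers
# ---------------------------------------------------------------------------

@dataclass
class SamplingFractions:
    """Per-state probability that an extant species in that state is sampled."""

    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if ((self.f <= 0) | (self.f > 1)).any():
            raise ValueError("sampling fractions must lie in (0, 1]")

    @classmethod
    def uniform(cls, f: float, n_states: int) -> "SamplingFractions":
        return cls(np.full(n_states, float(f)))


@dataclass
class RootSpec:
    """Root treatment: probability mass over root states.

    ``fixed(state)`` places all mass on one combination (the default analysis
    fixes the root at the all-ancestral combination, state 0);
    ``weights(w)`` supplies an arbitrary distribution.
    """

    weights: np.ndarray
    mode: str = "given-weights"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.min() < 0 or not math.isclose(self.weights.sum(), 1.0,
                                                      rel_tol=1e-9):
            raise ValueError("root weights must be non-negative and sum to 1")

    @classmethod
    def fixed(cls, state: int, n_states: int) -> "RootSpec":
        w = np.zeros(n_states)
        w[state] = 1.0
        return cls(w, mode="fixed-state")

    @classmethod
    def given(cls, weights: Sequence[float]) -> "RootSpec":
        return cls(np.asarray(weights, dtype=float))


class AnnotatedTree:
    """A rooted, bifurcating, time-calibrated tree with tip state indices.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``; edge lengths in Myr.
    tip_states:
        Mapping from taxon label to state index, or ``None`` for missing.
    metadata:
        Free-form provenance flags (simulators record truncation etc. here).
    """

    def __init__(self, tree: dendropy.Tree,
                 tip_states: Mapping[str, int | None],
                 metadata: dict | None = None) -> None:
        self.tree = tree
        self.tip_states = dict(tip_states)
        self.metadata = metadata or {}
        self._arrays = None

    # -- basic summaries ----------------------------------------------------
    @property
    def taxon_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def root_age(self) -> float:
        self.tree.calc_node_root_distances()
        return max(lf.root_distance for lf in self.tree.leaf_node_iter())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        self.tree.calc_node_root_distances()
        depths = [lf.root_distance for lf in self.tree.leaf_node_iter()]
        dmax = max(depths)
        return dmax == 0 or (dmax - min(depths)) <= rtol * dmax

    def observed_states(self) -> set[int]:
        return {s for s in self.tip_states.values() if s is not None}

    def drop_unscored(self) -> "AnnotatedTree":
        """Remove tips with missing states (the default pipeline behaviour)."""
        keep = [lab for lab, s in self.tip_states.items() if s is not None]
        if len(keep) == len(self.tip_states):
            return self
        t = self.tree.clone(depth=1)
        t.retain_taxa_with_labels(keep)
        states = {lab: self.tip_states[lab] for lab in keep}
        return AnnotatedTree(t, states, dict(self.metadata))

    # -- flattened arrays for the likelihood sweeps -------------------------
    def arrays(self) -> "_TreeArrays":
        if self._arrays is None:
            self._arrays = _TreeArrays(self)
        return self._arrays


class _TreeArrays:
    """Post-order index arrays and node heights for a bifurcating tree."""

    def __init__(self, atree: AnnotatedTree) -> None:
        tree = atree.tree
        tree.calc_node_root_distances()
        nodes = list(tree.postorder_node_iter())
        depth = max(n.root_distance for n in nodes if n.is_leaf())
        self.n_nodes = len(nodes)
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.height = np.array([depth - n.root_distance for n in nodes])
        self.is_tip = np.array([n.is_leaf() for n in nodes])
        self.children = np.full((self.n_nodes, 2), -1, dtype=int)
        self.tip_label = [None] * self.n_nodes
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        for i, n in enumerate(nodes):
            if n.is_leaf():
                self.tip_label[i] = n.taxon.label
            else:
                ch = n.child_nodes()
                if len(ch) != 2:
                    raise ValueError(
                        f"tree must be strictly bifurcating; node has {len(ch)} children")
                self.children[i] = [self.index[id(c)] for c in ch]
                for c in ch:
                    self.parent[self.index[id(c)]] = i
        self.root = self.n_nodes - 1
        self.depth = depth
        # processing order: by height, tips before internals at equal height,
        # stable post-order within ties
        order = sorted(range(self.n_nodes),
                       key=lambda i: (self.height[i], not self.is_tip[i], i))
        self.order = np.array(order, dtype=int)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def tip_initialize(state: int | None, sampling: SamplingFractions
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Initial (D, E) vectors at a tip.

    A tip observed in state ``s`` has ``D_s = f_s`` and zero elsewhere; a tip
    with missing state has ``D_i = f_i`` for all i.  ``E = 1 - f`` in either
    case.
    """
    f = sampling.f
    E = 1.0 - f
    if state is None:
        return f.copy(), E
    D = np.zeros_like(f)
    D[state] = f[state]
    return D, E


def _joint_rhs(rateset: RateSet):
    lam, mu = rateset.lam, rateset.mu
    Qoff = rateset.q_off()
    qout = Qoff.sum(axis=1)
    tot = lam + mu + qout
    n = rateset.n_states

    def rhs(t, y):
        D, E = y[:n], y[n:]
        dE = mu - tot * E + lam * E * E + Qoff @ E
        dD = -tot * D + 2.0 * lam * E * D + Qoff @ D
        return np.concatenate([dD, dE])

    return rhs


def integrate_branch(D: np.ndarray, E: np.ndarray, rateset: RateSet,
                     duration: float, rtol: float = ODE_RTOL,
                     atol: float = ODE_ATOL) -> tuple[np.ndarray, np.ndarray]:
    """Propagate (D, E) rootward along a branch of the given duration.

    Uses an adaptive solver on the joint nonlinear system.  Zero duration
    returns the inputs unchanged.
    """
    if duration < 0:
        raise ValueError("branch duration must be non-negative")
    if duration == 0:
        return D.copy(), E.copy()
    n = rateset.n_states
    y0 = np.concatenate([D, E])
    sol = solve_ivp(_joint_rhs(rateset), (0.0, duration), y0,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"branch ODE integration failed: {sol.message}")
    y = sol.y[:, -1]
    return y[:n], np.clip(y[n:], 0.0, 1.0)


def combine_node(D_left: np.ndarray, D_right: np.ndarray, rateset: RateSet
                 ) -> np.ndarray:
    """Node convolution: ``D_i = lambda_i * D_left,i * D_right,i``."""
    return rateset.lam * D_left * D_right


def _node_lambda(rateset: RateSet) -> np.ndarray:
    """Speciation factor applied at internal nodes.

    In the degenerate ``lambda == 0`` limit the process cannot generate the
    tree at all; the model then reduces to pure character evolution on a
    *given* tree and the node speciation density is dropped, recovering the
    Mk pruning likelihood.  With any positive speciation rate the usual
    ``lambda_i`` factor applies.
    """
    if (rateset.lam > 0).any():
        return rateset.lam
    return np.ones_like(rateset.lam)


# ---------------------------------------------------------------------------
# Fast synchronous sweep
# ---------------------------------------------------------------------------

def _sweep(atree: AnnotatedTree, rateset: RateSet,
           sampling: SamplingFractions, max_step: float,
           return_E: bool = False):
    """Advance all live branch D columns and the shared E from tips to root.

    Returns (D_root, log_scale, E_root) where the root likelihood vector is
    ``D_root * exp(log_scale)``, or None entries if some subtree has zero
    likelihood mass.
    """
    arr = atree.arrays()
    n = rateset.n_states
    lam, mu = rateset.lam, rateset.mu
    lam_node = _node_lambda(rateset)
    Qoff = rateset.q_off()
    qout = Qoff.sum(axis=1)
    tot = lam + mu + qout

    # explicit RK4 is only stable for steps small against the fastest total
    # rate; cap the step so optimiser excursions to large rates stay stable
    rate_scale = float(tot.max() + rateset.lam.max())
    if rate_scale > 0:
        max_step = min(max_step, 1.0 / rate_scale)

    ntips = int(arr.is_tip.sum())
    X = np.zeros((n, ntips + 1))
    col_log = np.zeros(ntips + 1)
    col_of = {}
    node_of = {}
    n_active = 0

    E = 1.0 - sampling.f
    t = 0.0

    def rhs(XA, Ev):
        dE = mu - tot * Ev + lam * Ev * Ev + Qoff @ Ev
        diag = -tot + 2.0 * lam * Ev
        dX = Qoff @ XA + diag[:, None] * XA
        return dX, dE

    def advance(t0, t1):
        nonlocal E
        if t1 <= t0:
            return
        span = t1 - t0
        nsub = max(1, int(math.ceil(span / max_step)))
        h = span / nsub
        XA = X[:, :n_active]
        Ev = E
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(nsub):
                k1x, k1e = rhs(XA, Ev)
                k2x, k2e = rhs(XA + 0.5 * h * k1x, Ev + 0.5 * h * k1e)
                k3x, k3e = rhs(XA + 0.5 * h * k2x, Ev + 0.5 * h * k2e)
                k4x, k4e = rhs(XA + h * k3x, Ev + h * k3e)
                XA = XA + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
                Ev = Ev + (h / 6.0) * (k1e + 2 * k2e + 2 * k3e + k4e)
        X[:, :n_active] = XA
        E = np.clip(Ev, 0.0, 1.0)

    def alloc(node):
        nonlocal n_active
        c = n_active
        n_active += 1
        col_of[node] = c
        node_of[c] = node
        col_log[c] = 0.0
        return c

    def free(node):
        nonlocal n_active
        c = col_of.pop(node)
        last = n_active - 1
        if c != last:
            X[:, c] = X[:, last]
            col_log[c] = col_log[last]
            moved = node_of[last]
            node_of[c] = moved
            col_of[moved] = c
        node_of.pop(last)
        n_active -= 1

    for node in arr.order:
        advance(t, arr.height[node])
        t = arr.height[node]
        if arr.is_tip[node]:
            state = atree.tip_states.get(arr.tip_label[node])
            D, _ = tip_initialize(state, sampling)
            c = alloc(node)
            X[:, c] = D
        else:
            cl, cr = arr.children[node]
            Dn = lam_node * X[:, col_of[cl]] * X[:, col_of[cr]]
            logn = col_log[col_of[cl]] + col_log[col_of[cr]]
            free(cl)
            free(cr)
            m = Dn.max()
            if not np.isfinite(m) or m <= 0.0:
                return None, None, None
            c = alloc(node)
            X[:, c] = Dn / m
            col_log[c] = logn + math.log(m)

    assert n_active == 1
    c = col_of[arr.root]
    return X[:, c].copy(), float(col_log[c]), E.copy()


def _per_branch(atree: AnnotatedTree, rateset: RateSet,
                sampling: SamplingFractions, rtol: float, atol: float):
    """Reference post-order recursion using the adaptive per-branch solver."""
    arr = atree.arrays()
    lam_node = _node_lambda(rateset)
    D_at = {}
    E_at = {}
    log_at = {}
    self_len = np.zeros(arr.n_nodes)
    for i in range(arr.n_nodes):
        p = arr.parent[i]
        if p >= 0:
            self_len[i] = arr.height[p] - arr.height[i]
    for node in arr.order:
        if arr.is_tip[node]:
            D, E = tip_initialize(atree.tip_states.get(arr.tip_label[node]),
                                  sampling)
            log_at[node] = 0.0
        else:
            cl, cr = arr.children[node]
            Dl, El = integrate_branch(D_at.pop(cl), E_at.pop(cl), rateset,
                                      self_len[cl], rtol, atol)
            Dr, _ = integrate_branch(D_at.pop(cr), E_at.pop(cr), rateset,
                                     self_len[cr], rtol, atol)
            D = lam_node * Dl * Dr
            E = El
            log_at[node] = log_at.pop(cl) + log_at.pop(cr)
            m = D.max()
            if not np.isfinite(m) or m <= 0.0:
                return None, None, None
            D = D / m
            log_at[node] += math.log(m)
        D_at[node] = D
        E_at[node] = E
    r = arr.root
    return D_at[r], log_at[r], E_at[r]


def loglik(atree: AnnotatedTree, rateset: RateSet,
           sampling: SamplingFractions, root: RootSpec,
           condition_on_survival: bool = False,
           method: str = "fast", max_step: float = SWEEP_MAX_STEP,
           rtol: float = ODE_RTOL, atol: float = ODE_ATOL,
           check_ultrametric: bool = True) -> float:
    """Log-likelihood of the tip states under the multistate SSE model.

    Returns ``-inf`` when the root states permitted by ``root`` carry zero
    likelihood mass (e.g. a fixed root state incompatible with the data under
    zero transition rates).

    With ``condition_on_survival=True`` the likelihood is divided by
    ``lambda_i * (1 - E_i(T))**2`` per root state, conditioning on the root
    lineage leaving two surviving sampled-able descendants; the default, like
    the analyses this package reproduces, does not condition.
    """
    if rateset.n_states != sampling.f.shape[0]:
        raise ValueError("rateset and sampling fraction dimensions differ")
    if check_ultrametric and not atree.is_ultrametric():
        raise ValueError("tree is not ultrametric within tolerance")
    if method == "fast":
        D, logsc, E = _sweep(atree, rateset, sampling, max_step)
    elif method == "per-branch":
        D, logsc, E = _per_branch(atree, rateset, sampling, rtol, atol)
    else:
        raise ValueError(f"unknown method {method!r}")
    if D is None:
        return -math.inf
    if condition_on_survival:
        denom = rateset.lam * (1.0 - E) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            D = np.where(denom > 0, D / denom, 0.0)
    mass = float(root.weights @ D)
    if mass <= 0.0 or not np.isfinite(mass):
        return -math.inf
    return math.log(mass) + logsc


# ---------------------------------------------------------------------------
# Marginal ancestral-state reconstruction
# ---------------------------------------------------------------------------

def _branch_propagators(atree: AnnotatedTree, rateset: RateSet,
                        sampling: SamplingFractions, rtol: float,
                        atol: float) -> dict[int, np.ndarray]:
    """Matrix Phi_b per branch with D_top = Phi_b @ D_bottom.

    The D equation is linear given the shared E trajectory, so each branch
    has an exact propagator; E(t) is solved once over the tree depth and
    interpolated.
    """
    arr = atree.arrays()
    n = rateset.n_states
    lam, mu = rateset.lam, rateset.mu
    Qoff = rateset.q_off()
    qout = Qoff.sum(axis=1)
    tot = lam + mu + qout

    def e_rhs(t, E):
        return mu - tot * E + lam * E * E + Qoff @ E

    E0 = 1.0 - sampling.f
    esol = solve_ivp(e_rhs, (0.0, max(arr.depth, 1e-12)), E0, method="LSODA",
                     rtol=rtol, atol=atol, dense_output=True)
    if not esol.success:
        raise RuntimeError(f"E integration failed: {esol.message}")

    def phi_rhs(t, y):
        Phi = y.reshape(n, n)
        E = np.clip(esol.sol(t), 0.0, 1.0)
        B = Qoff + np.diag(-tot + 2.0 * lam * E)
        return (B @ Phi).ravel()

    phis = {}
    eye = np.eye(n).ravel()
    for i in range(arr.n_nodes):
        p = arr.parent[i]
        if p < 0:
            continue
        t0, t1 = arr.height[i], arr.height[p]
        if t1 <= t0:
            phis[i] = np.eye(n)
            continue
        sol = solve_ivp(phi_rhs, (t0, t1), eye, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"propagator integration failed: {sol.message}")
        phis[i] = sol.y[:, -1].reshape(n, n)
    return phis


def marginal_asr(atree: AnnotatedTree, rateset: RateSet,
                 sampling: SamplingFractions, root: RootSpec,
                 rtol: float = ODE_RTOL, atol: float = ODE_ATOL
                 ) -> dict[str | int, np.ndarray]:
    """Marginal ancestral-state probabilities for every node.

    Exploits the linearity of the D equation: with per-branch propagators
    ``Phi``, a single down-pass computes the conditional likelihoods and a
    single up-pass distributes the root weighting, giving for node ``v``
    ``P(v = i) ∝ U_v,i * D_v,i``.  Keys are taxon labels for tips and the
    post-order index for internal nodes; the root's entry is also available
    under the key ``"root"``.
    """
    arr = atree.arrays()
    lam = _node_lambda(rateset)
    phis = _branch_propagators(atree, rateset, sampling, rtol, atol)

    D = {}
    for node in arr.order:
        if arr.is_tip[node]:
            D[node], _ = tip_initialize(
                atree.tip_states.get(arr.tip_label[node]), sampling)
        else:
            cl, cr = arr.children[node]
            D[node] = lam * (phis[cl] @ D[cl]) * (phis[cr] @ D[cr])
            m = D[node].max()
            if m <= 0:
                raise ValueError("zero likelihood mass; cannot reconstruct")
            D[node] /= m

    U = {arr.root: root.weights.copy()}
    for node in arr.order[::-1]:
        if arr.is_tip[node]:
            continue
        cl, cr = arr.children[node]
        up = U[node]
        U[cl] = phis[cl].T @ (up * lam * (phis[cr] @ D[cr]))
        U[cr] = phis[cr].T @ (up * lam * (phis[cl] @ D[cl]))

    out: dict[str | int, np.ndarray] = {}
    for node in range(arr.n_nodes):
        p = U[node] * D[node]
        s = p.sum()
        if s <= 0:
            raise ValueError("zero marginal mass at a node")
        p = p / s
        key = arr.tip_label[node] if arr.is_tip[node] else node
        out[key] = p
    out["root"] = out[arr.root]
    return out


# ---------------------------------------------------------------------------
# Independent Mk oracle (lambda = mu = 0 limit), used by tests
# ---------------------------------------------------------------------------

def mk_loglik_expm(atree: AnnotatedTree, Q: np.ndarray,
                   root_weights: np.ndarray) -> float:
    """Continuous-time Markov (Mk) pruning log-likelihood via matrix
    exponentials — a closed-path oracle for the lambda = mu = 0 limit."""
    arr = atree.arrays()
    logsc = 0.0
    D = {}
    for node in arr.order:
        if arr.is_tip[node]:
            s = atree.tip_states.get(arr.tip_label[node])
            v = np.ones(Q.shape[0]) if s is None else np.eye(Q.shape[0])[s]
            D[node] = v
        else:
            cl, cr = arr.children[node]
            Pl = expm(Q * (arr.height[node] - arr.height[cl]))
            Pr = expm(Q * (arr.height[node] - arr.height[cr]))
            v = (Pl @ D[cl]) * (Pr @ D[cr])
            m = v.max()
            if m <= 0:
                return -math.inf
            logsc += math.log(m)
            D[node] = v / m
    mass = float(root_weights @ D[arr.root])
    if mass <= 0:
        return -math.inf
    return math.log(mass) + logsc
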