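"""Trait-combination state space, focal-area bipartitions and tied-rate models.

A suite of ``K`` binary characters defines ``2**K`` possible character-state
combinations.  Each combination is a vertex of the K-dimensional hypercube;
two combinations are adjacent (a single anagenetic transition can convert one
into the other) iff they differ in exactly one character.  For the six floral
characters studied here that gives 64 combinations and 192 undirected edges.

A *focal-area bipartition* divides the combinations into a focal set ``F`` and
its complement ``N``.  Focal sets are described by a mask string over
``{0, 1, *}``: a combination belongs to ``F`` iff it matches every non-``*``
position.  There are ``3**K - 1`` admissible masks (the all-``*`` mask does
not bipartition anything).

Rather than estimating one speciation, extinction and transition rate per
state (``(K+2) * 2**K`` parameters for the full multistate model — 512 at
K=6), rates are tied within the two sets.  A *rate model* is the combination
of a transition model (how the four set-level transition rates
``q_FF, q_NN, q_FN, q_NF`` are constrained) and a diversification model (how
``lambda_F, lambda_N, mu_F, mu_N`` are constrained).  The default registry
holds five transition and six diversification models, a 30-model grid, with
at most eight free parameters in the richest member.

Encoding convention
-------------------
A combination is written with character 1 leftmost, and the state index is
the binary number read left to right: ``001 -> 1``, ``010 -> 2``, ``111111 ->
63``.  Mask strings use the same positional order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "Bipartition",
    "RateSet",
    "TransitionModel",
    "DiversificationModel",
    "RateModelSpec",
    "TRANSITION_MODELS",
    "DIVERSIFICATION_MODELS",
    "encode_combination",
    "decode_state",
    "neighbors",
    "enumerate_bipartitions",
    "focal_members",
    "filter_viable",
    "build_rateset",
    "count_parameters",
    "full_model_parameter_count",
    "full_transition_parameter_count",
    "model_grid",
    "load_model_grid",
]


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpace:
    """The hypercube of ``2**n_chars`` binary-character combinations."""

    n_chars: int

    def __post_init__(self) -> None:
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")

    @property
    def n_states(self) -> int:
        return 1 << self.n_chars

    @property
    def states(self) -> range:
        return range(self.n_states)

    def bit(self, state: int, char: int) -> int:
        """State of character ``char`` (0-based, leftmost character first)."""
        return (state >> (self.n_chars - 1 - char)) & 1

    def encode(self, bits: Sequence[int]) -> int:
        return encode_combination(bits, self)

    def decode(self, state: int) -> tuple[int, ...]:
        return decode_state(state, self)

    def neighbors(self, state: int) -> frozenset[int]:
        return neighbors(state, self)

    def edges(self, directed: bool = False) -> list[tuple[int, int]]:
        """Hypercube edges, ``K * 2**(K-1)`` undirected or twice that directed."""
        out = []
        for i in self.states:
            for j in self.neighbors(i):
                if directed or j > i:
                    out.append((i, j))
        return out


def encode_combination(bits: Sequence[int], space: StateSpace | None = None) -> int:
    """Map a 0/1 character vector to its state index.

    Character 1 (leftmost) is the highest-order bit, so ``(0,0,1) -> 1`` and
    ``(0,1,0) -> 2``.
    """
    if space is not None and len(bits) != space.n_chars:
        raise ValueError(
            f"expected {space.n_chars} characters, got {len(bits)}")
    state = 0
    for b in bits:
        if b not in (0, 1):
            raise ValueError(f"character states must be 0 or 1, got {b!r}")
        state = (state << 1) | int(b)
    return state


def decode_state(state: int, space: StateSpace) -> tuple[int, ...]:
    """Inverse of :func:`encode_combination`."""
    if not 0 <= state < space.n_states:
        raise ValueError(f"state {state} out of range for K={space.n_chars}")
    return tuple(space.bit(state, c) for c in range(space.n_chars))


def neighbors(state: int, space: StateSpace) -> frozenset[int]:
    """States reachable by flipping exactly one character (hypercube degree K)."""
    if not 0 <= state < space.n_states:
        raise ValueError(f"state {state} out of range for K={space.n_chars}")
    return frozenset(state ^ (1 << k) for k in range(space.n_chars))


# ---------------------------------------------------------------------------
# Bipartitions (focal areas)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bipartition:
    """Focal-area mask over ``{0,1,*}**K``; matches define the focal set F."""

    mask: str

    def __post_init__(self) -> None:
        if not self.mask:
            raise ValueError("mask must be non-empty")
        bad = set(self.mask) - set("01*")
        if bad:
            raise ValueError(f"mask may only contain 0, 1, *: got {sorted(bad)}")
        if set(self.mask) == {"*"}:
            raise ValueError("the all-* mask does not define a bipartition")

    @property
    def n_chars(self) -> int:
        return len(self.mask)

    @property
    def n_fixed(self) -> int:
        return sum(c != "*" for c in self.mask)

    def is_focal(self, state: int, space: StateSpace) -> bool:
        if len(self.mask) != space.n_chars:
            raise ValueError("mask length does not match state space")
        for char, m in enumerate(self.mask):
            if m != "*" and space.bit(state, char) != int(m):
                return False
        return True

    def focal_set(self, space: StateSpace) -> frozenset[int]:
        return focal_members(self.mask, space)

    def complement_set(self, space: StateSpace) -> frozenset[int]:
        return frozenset(space.states) - self.focal_set(space)


def focal_members(mask: str | Bipartition, space: StateSpace) -> frozenset[int]:
    """States matching every fixed position of the mask; ``|F| = 2**(#*)``."""
    bp = mask if isinstance(mask, Bipartition) else Bipartition(str(mask))
    return frozenset(s for s in space.states if bp.is_focal(s, space))


def enumerate_bipartitions(space: StateSpace) -> list[Bipartition]:
    """All ``3**K - 1`` focal-area masks, lexicographic order ('0' < '1' < '*')."""
    masks = itertools.product("01*", repeat=space.n_chars)
    return [Bipartition("".join(m)) for m in masks
            if set(m) != {"*"}]


def filter_viable(bipartitions: Iterable[Bipartition],
                  observed_states: Iterable[int],
                  space: StateSpace) -> list[Bipartition]:
    """Keep only bipartitions with at least one observed state on each side.

    Combinations unrepresented in the data cannot anchor a focal set: a mask
    whose focal (or non-focal) side contains no sampled species yields a
    degenerate model and is dropped before fitting.
    """
    obs = frozenset(observed_states)
    if not obs:
        raise ValueError("observed_states must be non-empty")
    out = []
    for bp in bipartitions:
        f = bp.focal_set(space)
        if obs & f and obs - f:
            out.append(bp)
    return out


# ---------------------------------------------------------------------------
# Rate sets
# ---------------------------------------------------------------------------

@dataclass
class RateSet:
    """Per-state speciation/extinction rates and the transition-rate matrix.

    ``Q`` has non-zero off-diagonals only on hypercube edges and rows summing
    to zero.  All rates are per lineage per Myr.
    """

    lam: np.ndarray
    mu: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        n = self.lam.shape[0]
        if self.mu.shape != (n,) or self.Q.shape != (n, n):
            raise ValueError("inconsistent RateSet dimensions")
        if (self.lam < 0).any() or (self.mu < 0).any():
            raise ValueError("lambda and mu must be non-negative")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal transition rates must be non-negative")

    @property
    def n_states(self) -> int:
        return self.lam.shape[0]

    @property
    def net_div(self) -> np.ndarray:
        """Net diversification r = lambda - mu, per state."""
        return self.lam - self.mu

    def q_off(self) -> np.ndarray:
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        return off

    def to_dict(self) -> dict:
        return {"lam": self.lam.tolist(), "mu": self.mu.tolist(),
                "Q": self.Q.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateSet":
        return cls(np.array(d["lam"]), np.array(d["mu"]), np.array(d["Q"]))


# ---------------------------------------------------------------------------
# Tied-rate model specifications
# ---------------------------------------------------------------------------
#
# A model constrains the four set-level transition rates and the four set-level
# diversification rates to linear combinations (non-negative coefficients) of a
# small set of free parameters.  Slot expressions are {symbol: coefficient}
# mappings, which is enough to express every model in the default registry
# (e.g. lambda_F = 2 * lambda_N for the "two/one" model, or
# lambda_F = r + mu_F for the equal-net-r model) while keeping every expanded
# rate automatically non-negative.

_TRANS_SLOTS = ("q_FF", "q_NN", "q_FN", "q_NF")
_DIV_SLOTS = ("lam_F", "lam_N", "mu_F", "mu_N")


def _expand_slots(slots: Mapping[str, Mapping[str, float]],
                  names: Sequence[str],
                  values: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for slot in names:
        expr = slots[slot]
        out[slot] = sum(coef * values[sym] for sym, coef in expr.items())
    return out


@dataclass(frozen=True)
class TransitionModel:
    """Constraint pattern on the set-level transition rates."""

    name: str
    params: tuple[str, ...]
    slots: Mapping[str, Mapping[str, float]] = field(hash=False)

    def expand(self, values: Mapping[str, float]) -> dict[str, float]:
        return _expand_slots(self.slots, _TRANS_SLOTS, values)

    @property
    def n_params(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class DiversificationModel:
    """Constraint pattern on the set-level speciation/extinction rates."""

    name: str
    params: tuple[str, ...]
    slots: Mapping[str, Mapping[str, float]] = field(hash=False)

    def expand(self, values: Mapping[str, float]) -> dict[str, float]:
        return _expand_slots(self.slots, _DIV_SLOTS, values)

    @property
    def n_params(self) -> int:
        return len(self.params)


def _tm(name, params, q_FF, q_NN, q_FN, q_NF):
    def parse(e):
        if isinstance(e, str):
            return {e: 1.0}
        return dict(e)
    return TransitionModel(name, tuple(params), {
        "q_FF": parse(q_FF), "q_NN": parse(q_NN),
        "q_FN": parse(q_FN), "q_NF": parse(q_NF)})


def _dm(name, params, lam_F, lam_N, mu_F, mu_N):
    def parse(e):
        if isinstance(e, str):
            return {e: 1.0}
        return dict(e)
    return DiversificationModel(name, tuple(params), {
        "lam_F": parse(lam_F), "lam_N": parse(lam_N),
        "mu_F": parse(mu_F), "mu_N": parse(mu_N)})


#: Default five-member transition-model family.
TRANSITION_MODELS: dict[str, TransitionModel] = {m.name: m for m in [
    # single rate everywhere
    _tm("one-rate", ("q",), "q", "q", "q", "q"),
    # one rate within sets, one between
    _tm("within-between", ("q_w", "q_b"), "q_w", "q_w", "q_b", "q_b"),
    # free within-set rates, symmetric between-set rate
    _tm("equal", ("q_FF", "q_NN", "q_x"), "q_FF", "q_NN", "q_x", "q_x"),
    # shared within-set rate, free directional between-set rates
    _tm("outflow", ("q_w", "q_FN", "q_NF"), "q_w", "q_w", "q_FN", "q_NF"),
    # all four free
    _tm("free", ("q_FF", "q_NN", "q_FN", "q_NF"),
        "q_FF", "q_NN", "q_FN", "q_NF"),
]}

#: Default six-member diversification-model family.
DIVERSIFICATION_MODELS: dict[str, DiversificationModel] = {m.name: m for m in [
    # no state-dependent diversification
    _dm("all-equal", ("lam", "mu"), "lam", "lam", "mu", "mu"),
    # focal speciation free, shared extinction
    _dm("free-lambda", ("lam_F", "lam_N", "mu"), "lam_F", "lam_N", "mu", "mu"),
    # shared speciation, free extinction
    _dm("free-mu", ("lam", "mu_F", "mu_N"), "lam", "lam", "mu_F", "mu_N"),
    # all four free
    _dm("free", ("lam_F", "lam_N", "mu_F", "mu_N"),
        "lam_F", "lam_N", "mu_F", "mu_N"),
    # focal speciation fixed at twice the non-focal rate, shared extinction
    _dm("two/one", ("lam_N", "mu"), {"lam_N": 2.0}, "lam_N", "mu", "mu"),
    # equal net diversification r, free turnover (lam = r + mu per set)
    _dm("equal-r", ("r", "mu_F", "mu_N"),
        {"r": 1.0, "mu_F": 1.0}, {"r": 1.0, "mu_N": 1.0}, "mu_F", "mu_N"),
]}


@dataclass(frozen=True)
class RateModelSpec:
    """A (transition model, diversification model) pair from the grid."""

    transition: TransitionModel
    diversification: DiversificationModel

    @property
    def name(self) -> str:
        return f"{self.diversification.name}+{self.transition.name}"

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.diversification.params + self.transition.params

    @property
    def n_params(self) -> int:
        return self.diversification.n_params + self.transition.n_params

    def expand(self, params: Sequence[float]) -> dict[str, float]:
        """Map a free-parameter vector to the eight set-level rates."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters, got {params.shape}")
        if (params < 0).any():
            raise ValueError("rate parameters must be non-negative")
        values = dict(zip(self.param_names, params))
        out = self.diversification.expand(values)
        out.update(self.transition.expand(values))
        return out


def model_grid(transition_names: Sequence[str] | None = None,
               diversification_names: Sequence[str] | None = None,
               registry_t: Mapping[str, TransitionModel] = TRANSITION_MODELS,
               registry_d: Mapping[str, DiversificationModel] = DIVERSIFICATION_MODELS,
               ) -> list[RateModelSpec]:
    """Cross-product model grid; the full default registry gives 5 x 6 = 30."""
    t_names = list(transition_names or registry_t)
    d_names = list(diversification_names or registry_d)
    return [RateModelSpec(registry_t[t], registry_d[d])
            for d in d_names for t in t_names]


def load_model_grid(source) -> list[RateModelSpec]:
    """Build a model grid from a plain-text config (JSON path, file or dict).

    Expected keys: ``transition_models`` and ``diversification_models``, each
    either a list of registry names or a mapping ``name -> {params: [...],
    slots: {slot: {symbol: coef} | "symbol"}}`` defining new tied patterns, so
    alternative model families can be swapped in without code changes.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        if hasattr(source, "read"):
            cfg = json.load(source)
        else:
            with open(source) as fh:
                cfg = json.load(fh)
    else:
        cfg = dict(source)

    def build(spec, registry, factory):
        if isinstance(spec, list):
            return {name: registry[name] for name in spec}
        out = {}
        for name, body in spec.items():
            if body is None:
                out[name] = registry[name]
            else:
                slots = body["slots"]
                out[name] = factory(name, body["params"],
                                    *[slots[s] for s in
                                      (_TRANS_SLOTS if factory is _tm
                                       else _DIV_SLOTS)])
        return out

    reg_t = build(cfg.get("transition_models", list(TRANSITION_MODELS)),
                  TRANSITION_MODELS, _tm)
    reg_d = build(cfg.get("diversification_models", list(DIVERSIFICATION_MODELS)),
                  DIVERSIFICATION_MODELS, _dm)
    return model_grid(list(reg_t), list(reg_d), reg_t, reg_d)


# ---------------------------------------------------------------------------
# Expansion to full per-state rates
# ---------------------------------------------------------------------------

def build_rateset(bipartition: Bipartition,
                  spec: RateModelSpec,
                  params: Sequence[float],
                  space: StateSpace) -> RateSet:
    """Expand a tied-rate model into full per-state lambda, mu and Q.

    Every hypercube edge (i, j) receives the set-level rate of its endpoint
    classes (q_FF, q_NN, q_FN or q_NF); non-edges are zero; the Q diagonal is
    minus the row sum.  Per-state lambda and mu follow set membership.
    """
    rates = spec.expand(params)
    focal = bipartition.focal_set(space)
    n = space.n_states
    in_f = np.array([s in focal for s in space.states])

    lam = np.where(in_f, rates["lam_F"], rates["lam_N"])
    mu = np.where(in_f, rates["mu_F"], rates["mu_N"])

    Q = np.zeros((n, n))
    for i in space.states:
        for j in neighbors(i, space):
            if in_f[i]:
                Q[i, j] = rates["q_FF"] if in_f[j] else rates["q_FN"]
            else:
                Q[i, j] = rates["q_NF"] if in_f[j] else rates["q_NN"]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateSet(lam, mu, Q)


# ---------------------------------------------------------------------------
# Parameter counting
# ---------------------------------------------------------------------------

def count_parameters(spec: RateModelSpec) -> int:
    """Free parameters of a tied-rate model (at most 8 in the default grid)."""
    return spec.n_params


def full_transition_parameter_count(space: StateSpace,
                                    directed: bool = True) -> int:
    """Transition parameters of the untied multistate model.

    One rate per directed hypercube edge by default (``K * 2**K``; 384 at
    K=6); ``directed=False`` counts one rate per undirected edge
    (``K * 2**(K-1)``; 12 at K=3).
    """
    undirected = space.n_chars * (1 << (space.n_chars - 1))
    return 2 * undirected if directed else undirected


def full_model_parameter_count(space: StateSpace, directed: bool = True) -> int:
    """Total parameters of the untied model: per-state lambda and mu plus the
    per-edge transition rates (``(K+2) * 2**K`` directed; 512 at K=6)."""
    return 2 * space.n_states + full_transition_parameter_count(space, directed)
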