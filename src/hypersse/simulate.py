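"""Stochastic simulation of state-dependent birth–death-with-transition
processes, stationary frequencies, and trajectory summaries.

Two simulators share the same model (a lineage in state ``i`` speciates at
``lambda_i``, goes extinct at ``mu_i`` and moves to a hypercube neighbour
``j`` at ``q_ij``) and the same exact event scheduling (Gillespie algorithm:
exponential waiting times, event chosen proportionally to rate):

``simulate_tree``
    Tracks every lineage and returns the full tree with extinct lineages
    marked — used for parametric-bootstrap style analyses where the tree is
    subsequently pruned to a fixed number of extant tips and refitted.

``simulate_counts``
    Tracks only the per-state lineage counts, recording them on a regular
    time grid — far cheaper, used for long-horizon frequency trajectories
    and first-origin times.

The long-run expectation of both is governed by the linear mean dynamics
``dn/dt = A n`` with ``A_ii = r_i - sum_j q_ij`` and ``A_ij = q_ji``; the
normalised dominant right eigenvector of ``A`` gives the stationary
(equilibrium) state frequencies and its dominant eigenvalue the asymptotic
growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg

from .likelihood import AnnotatedTree
from .trait_space import RateSet

__all__ = [
    "SimConfig",
    "Trajectory",
    "simulate_tree",
    "prune_subsample",
    "simulate_counts",
    "simulate_counts_ensemble",
    "stationary_frequencies",
    "growth_rate",
    "origin_time_summary",
    "trajectories_to_frame",
]

#: default lineage cap before truncation / renormalisation
MAX_LINEAGES = 500_000


@dataclass
class SimConfig:
    """Configuration shared by both simulators.

    ``duration`` is in Myr (e.g. 136 to the present, 151 to reach 15 Myr into
    the future); ``record_interval`` sets the counts-recording grid; the
    ``seed`` is mandatory so every run is reproducible.  When a counts run
    exceeds ``max_lineages`` it is either stopped (``renormalize=False``) or
    hypergeometrically downsampled to half the cap with the removed factor
    accumulated on a log scale, which preserves state proportions.
    """

    rateset: RateSet
    duration: float
    root_state: int = 0
    record_interval: float = 1.0
    n_reps: int = 1
    seed: int = 0
    max_lineages: int = MAX_LINEAGES
    renormalize: bool = False
    subsample: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        n_rec = self.duration / self.record_interval
        if abs(n_rec - round(n_rec)) > 1e-9:
            raise ValueError("record_interval must divide duration")
        if not 0 <= self.root_state < self.rateset.n_states:
            raise ValueError("root_state out of range")


@dataclass
class Trajectory:
    """Counts-only realisation: per-state counts on a regular time grid."""

    times: np.ndarray
    counts: np.ndarray            # (n_records, n_states)
    log_scale: np.ndarray         # log of cumulative renormalisation factors
    first_origin: np.ndarray      # per state, Myr; NaN if never reached
    extinct: bool
    truncated: bool = False
    renormalized: bool = False

    @property
    def surviving(self) -> bool:
        return not self.extinct

    def proportions(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)

    def log_total(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.counts.sum(axis=1)) + self.log_scale


def _event_tables(rateset: RateSet):
    """Per-state total rate and cumulative event distribution.

    Event index 0 = speciation, 1 = extinction, 2.. = transition to the
    corresponding target state (only states with q > 0 listed).
    """
    n = rateset.n_states
    Qoff = rateset.q_off()
    targets = []
    cumw = []
    total = np.zeros(n)
    for i in range(n):
        tg = np.nonzero(Qoff[i])[0]
        w = np.concatenate([[rateset.lam[i], rateset.mu[i]], Qoff[i, tg]])
        total[i] = w.sum()
        cw = np.cumsum(w)
        targets.append(tg)
        cumw.append(cw)
    return total, targets, cumw


# ---------------------------------------------------------------------------
# Full-tree simulator
# ---------------------------------------------------------------------------

def simulate_tree(config: SimConfig,
                  rng: np.random.Generator | None = None) -> AnnotatedTree:
    """Exact birth–death-with-transitions simulation keeping the tree.

    Returns an :class:`AnnotatedTree` whose tips carry states; extinct tips
    are annotated (``metadata['extinct_labels']`` and per-leaf annotation).
    ``metadata`` flags total extinction and cap truncation.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rs = config.rateset
    n_states = rs.n_states
    total_rate, targets, cumw = _event_tables(rs)

    # lineage records: parent lineage, birth time, end time, fate, state
    parent = [-1]
    t_birth = [0.0]
    t_end = [None]
    fate = [None]           # "speciation" | "extinction" | None (extant)
    state_of = [config.root_state]

    active_by_state: list[list[int]] = [[] for _ in range(n_states)]
    active_by_state[config.root_state].append(0)
    n_by_state = np.zeros(n_states, dtype=float)
    n_by_state[config.root_state] = 1
    n_active = 1
    truncated = False

    t = 0.0
    T = config.duration
    while n_active > 0:
        rates = n_by_state * total_rate
        R = rates.sum()
        if R <= 0:
            break
        t_next = t + rng.exponential(1.0 / R)
        if t_next > T:
            t = T
            break
        t = t_next
        s = int(np.searchsorted(np.cumsum(rates), rng.uniform(0, R),
                                side="right"))
        s = min(s, n_states - 1)
        pool = active_by_state[s]
        idx = rng.integers(len(pool))
        lin = pool[idx]
        u = rng.uniform(0, total_rate[s])
        ev = int(np.searchsorted(cumw[s], u, side="right"))
        if ev == 0:  # speciation
            pool[idx] = pool[-1]
            pool.pop()
            t_end[lin] = t
            fate[lin] = "speciation"
            for _ in range(2):
                parent.append(lin)
                t_birth.append(t)
                t_end.append(None)
                fate.append(None)
                state_of.append(s)
                pool.append(len(parent) - 1)
            n_by_state[s] += 1
            n_active += 1
            if n_active > config.max_lineages:
                truncated = True
                break
        elif ev == 1:  # extinction
            pool[idx] = pool[-1]
            pool.pop()
            t_end[lin] = t
            fate[lin] = "extinction"
            n_by_state[s] -= 1
            n_active -= 1
        else:  # transition
            tgt = int(targets[s][ev - 2])
            pool[idx] = pool[-1]
            pool.pop()
            active_by_state[tgt].append(lin)
            state_of[lin] = tgt
            n_by_state[s] -= 1
            n_by_state[tgt] += 1

    end_time = t if (n_active == 0 or truncated) else T
    for lin in range(len(parent)):
        if t_end[lin] is None:
            t_end[lin] = end_time

    return _records_to_tree(parent, t_birth, t_end, fate, state_of,
                            all_extinct=(n_active == 0), truncated=truncated,
                            duration=end_time)


def _records_to_tree(parent, t_birth, t_end, fate, state_of,
                     all_extinct: bool, truncated: bool,
                     duration: float) -> AnnotatedTree:
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = {}
    tip_states: dict[str, int | None] = {}
    extinct_labels = []
    n_lin = len(parent)
    for lin in range(n_lin):
        node = dendropy.Node()
        node.edge.length = t_end[lin] - t_birth[lin]
        nodes[lin] = node
    for lin in range(n_lin):
        if parent[lin] >= 0:
            nodes[parent[lin]].add_child(nodes[lin])
    for lin in range(n_lin):
        if fate[lin] != "speciation":  # a leaf: extant or extinct
            label = f"t{lin}"
            taxon = taxon_ns.new_taxon(label)
            nodes[lin].taxon = taxon
            tip_states[label] = state_of[lin]
            if fate[lin] == "extinction":
                extinct_labels.append(label)
                nodes[lin].annotations.add_new("extinct", "1")
    tree.seed_node = nodes[0]
    meta = {"all_extinct": all_extinct, "truncated": truncated,
            "duration": duration, "extinct_labels": extinct_labels}
    return AnnotatedTree(tree, tip_states, meta)


def prune_subsample(atree: AnnotatedTree, n: int,
                    rng: np.random.Generator) -> AnnotatedTree:
    """Drop extinct lineages and keep ``n`` extant tips uniformly at random.

    Branch lengths along retained paths are preserved (unifurcations produced
    by pruning are suppressed by summing edge lengths), so the result is
    ultrametric whenever the extant tree is.
    """
    extinct = set(atree.metadata.get("extinct_labels", []))
    extant = [lab for lab in atree.tip_states if lab not in extinct]
    if len(extant) < n:
        raise ValueError(f"only {len(extant)} extant tips; cannot keep {n}")
    keep = list(rng.choice(extant, size=n, replace=False))
    tree = atree.tree.clone(depth=1)
    tree.retain_taxa_with_labels(keep)
    # collapse a leftover single-child root carrying the stem
    seed = tree.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (seed.edge.length or 0.0)
        tree.seed_node = child
        child.parent_node = None
        seed = child
    states = {lab: atree.tip_states[lab] for lab in keep}
    meta = dict(atree.metadata)
    meta["extinct_labels"] = []
    meta["subsampled_from"] = len(extant)
    return AnnotatedTree(tree, states, meta)


# ---------------------------------------------------------------------------
# Counts-only simulator
# ---------------------------------------------------------------------------

def simulate_counts(config: SimConfig,
                    rng: np.random.Generator | None = None) -> Trajectory:
    """Markov jump process on the per-state count vector.

    Exact Gillespie simulation; only counts are tracked, recorded at
    ``record_interval`` spacing, plus the exact first time each state's count
    becomes positive.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rs = config.rateset
    n_states = rs.n_states
    total_rate, targets, cumw = _event_tables(rs)

    n = np.zeros(n_states, dtype=np.int64)
    n[config.root_state] = 1
    first = np.full(n_states, np.nan)
    first[config.root_state] = 0.0

    times = np.arange(0.0, config.duration + 1e-9, config.record_interval)
    counts = np.zeros((len(times), n_states), dtype=np.int64)
    log_scale_rec = np.zeros(len(times))
    rec = 0
    log_scale = 0.0
    truncated = False
    renormalized = False

    t = 0.0
    T = config.duration
    while True:
        rates = n * total_rate
        R = rates.sum()
        t_next = t + (rng.exponential(1.0 / R) if R > 0 else math.inf)
        while rec < len(times) and times[rec] <= min(t_next, T) + 1e-12:
            counts[rec] = n
            log_scale_rec[rec] = log_scale
            rec += 1
        if t_next > T or R <= 0:
            break
        t = t_next
        s = int(np.searchsorted(np.cumsum(rates), rng.uniform(0, R),
                                side="right"))
        s = min(s, n_states - 1)
        u = rng.uniform(0, total_rate[s])
        ev = int(np.searchsorted(cumw[s], u, side="right"))
        if ev == 0:
            n[s] += 1
        elif ev == 1:
            n[s] -= 1
        else:
            tgt = int(targets[s][ev - 2])
            n[s] -= 1
            n[tgt] += 1
            if n[tgt] > 0 and math.isnan(first[tgt]):
                first[tgt] = t
        ntot = int(n.sum())
        if ntot > config.max_lineages:
            if not config.renormalize:
                truncated = True
                break
            target_total = config.max_lineages // 2
            n = rng.multivariate_hypergeometric(n, target_total)
            log_scale += math.log(ntot / target_total)
            renormalized = True

    # fill any remaining records (extinction or truncation before the end)
    while rec < len(times):
        counts[rec] = n if not truncated else counts[max(rec - 1, 0)]
        log_scale_rec[rec] = log_scale
        rec += 1

    return Trajectory(times=times, counts=counts, log_scale=log_scale_rec,
                      first_origin=first, extinct=bool(n.sum() == 0),
                      truncated=truncated, renormalized=renormalized)


def simulate_counts_ensemble(config: SimConfig) -> list[Trajectory]:
    """Independent replicates with per-replicate RNG substreams derived from
    the master seed."""
    ss = np.random.SeedSequence(config.seed)
    return [simulate_counts(config, np.random.default_rng(child))
            for child in ss.spawn(config.n_reps)]


# ---------------------------------------------------------------------------
# Stationary frequencies and growth rate
# ---------------------------------------------------------------------------

def _growth_matrix(rateset: RateSet) -> np.ndarray:
    Qoff = rateset.q_off()
    A = Qoff.T.copy()
    np.fill_diagonal(A, rateset.net_div - Qoff.sum(axis=1))
    return A


def stationary_frequencies(rateset: RateSet, tol: float = 1e-9) -> np.ndarray:
    """Normalised dominant right eigenvector of the mean-growth matrix.

    The expected counts obey ``dn/dt = A n``; as t grows, state proportions
    converge to the eigenvector of A's dominant eigenvalue.  Raises if the
    dominant eigenpair is complex or defective beyond tolerance.
    """
    A = _growth_matrix(rateset)
    vals, vecs = scipy.linalg.eig(A)
    k = int(np.argmax(vals.real))
    lead = vals[k]
    if abs(lead.imag) > tol * max(1.0, abs(lead.real)):
        raise ValueError(f"dominant eigenvalue is complex: {lead}")
    v = vecs[:, k]
    if np.abs(v.imag).max() > tol:
        raise ValueError("dominant eigenvector is complex")
    v = v.real
    if v.sum() < 0:
        v = -v
    if v.min() < -tol:
        raise ValueError("dominant eigenvector changes sign")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def growth_rate(rateset: RateSet) -> float:
    """Dominant eigenvalue of the mean-growth matrix (per Myr)."""
    A = _growth_matrix(rateset)
    vals = scipy.linalg.eigvals(A)
    return float(vals.real.max())


# ---------------------------------------------------------------------------
# Trajectory summaries
# ---------------------------------------------------------------------------

def origin_time_summary(trajectories: Sequence[Trajectory],
                        states: Iterable[int],
                        exclude_root_state: int | None = None) -> dict:
    """Median and 95% interval of the first time any queried state appears.

    Replicates in which no queried state ever appears are censored and
    reported separately rather than folded into the quantiles.
    """
    states = [s for s in set(states) if s != exclude_root_state]
    if not states:
        raise ValueError("empty query state set")
    reached = []
    censored = 0
    for tr in trajectories:
        f = tr.first_origin[states]
        if np.isnan(f).all():
            censored += 1
        else:
            reached.append(np.nanmin(f))
    out = {"n_reached": len(reached), "n_censored": censored}
    if reached:
        arr = np.asarray(reached)
        out.update(median=float(np.median(arr)),
                   q025=float(np.quantile(arr, 0.025)),
                   q975=float(np.quantile(arr, 0.975)))
    return out


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format table: replicate, time_Myr, state, count."""
    frames = []
    for rep, tr in enumerate(trajectories):
        nt, ns = tr.counts.shape
        frames.append(pd.DataFrame({
            "replicate": np.repeat(rep, nt * ns),
            "time_Myr": np.repeat(tr.times, ns),
            "state": np.tile(np.arange(ns), nt),
            "count": tr.counts.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)
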