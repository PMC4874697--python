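"""Maximum-likelihood fitting over the bipartition x model grid, AIC ranking,
Akaike weights and model-averaged rates.

Every (focal-area bipartition, tied-rate model) pair is fitted independently
to the same tree and tip data, so likelihoods — and therefore AIC scores and
Akaike weights — are directly comparable across the whole search.  Rates are
optimised on a log scale with a bounded quasi-Newton method from several
starting points (a birth–death heuristic for the diversification rates, a
parsimony-based heuristic for the transition rates, and jittered variants).
Model-averaged per-state rates are the Akaike-weighted elementwise mean of
the expanded per-state/per-edge rates over all fitted models.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import AnnotatedTree, RootSpec, SamplingFractions, loglik
from .trait_space import (Bipartition, RateModelSpec, RateSet, StateSpace,
                          build_rateset, enumerate_bipartitions, filter_viable,
                          model_grid)

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_model",
    "fit_grid",
    "akaike_weights",
    "model_average",
    "rank_table",
    "write_model_table",
    "fits_to_json",
    "fits_from_json",
]

log = logging.getLogger(__name__)

#: optimisation bounds on each rate, per Myr
RATE_LO = 1e-9
RATE_HI = 10.0


@dataclass
class FitConfig:
    """Optimiser settings for a single model fit."""

    n_starts: int = 3
    maxiter: int = 200
    ftol: float = 1e-9
    gtol: float = 1e-6
    seed: int = 0
    max_step: float = 1.0          # sweep step (Myr) during optimisation
    condition_on_survival: bool = False
    extra_starts: tuple[tuple[float, ...], ...] = ()


@dataclass
class FitResult:
    """One fitted (bipartition, model) pair."""

    mask: str
    transition_model: str
    diversification_model: str
    param_names: tuple[str, ...]
    params: np.ndarray
    lnL: float
    k: int
    converged: bool
    set_rates: dict[str, float] = field(default_factory=dict)
    rateset: RateSet | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL

    @property
    def r_F(self) -> float:
        return self.set_rates["lam_F"] - self.set_rates["mu_F"]

    @property
    def r_N(self) -> float:
        return self.set_rates["lam_N"] - self.set_rates["mu_N"]


# ---------------------------------------------------------------------------
# Starting-value heuristics
# ---------------------------------------------------------------------------

def _fitch_changes(atree: AnnotatedTree, space: StateSpace) -> float:
    """Total parsimony state changes summed over characters (Fitch small
    parsimony on each binary character; unscored tips contribute both states)."""
    arr = atree.arrays()
    total = 0
    for char in range(space.n_chars):
        sets = {}
        changes = 0
        for node in arr.order:
            if arr.is_tip[node]:
                s = atree.tip_states.get(arr.tip_label[node])
                sets[node] = {0, 1} if s is None else {space.bit(s, char)}
            else:
                cl, cr = arr.children[node]
                inter = sets[cl] & sets[cr]
                if inter:
                    sets[node] = inter
                else:
                    sets[node] = sets[cl] | sets[cr]
                    changes += 1
        total += changes
    return float(total)


def _heuristic_rates(atree: AnnotatedTree, space: StateSpace
                     ) -> tuple[float, float, float]:
    """(lambda0, mu0, q0) from tree shape and character parsimony."""
    arr = atree.arrays()
    n = int(arr.is_tip.sum())
    depth = max(arr.depth, 1e-6)
    tree_len = sum(
        arr.height[arr.parent[i]] - arr.height[i]
        for i in range(arr.n_nodes) if arr.parent[i] >= 0)
    tree_len = max(float(tree_len), 1e-6)
    r0 = max(math.log(max(n, 2) / 2.0) / depth, 1e-5)
    mu0 = r0 / 4.0
    lam0 = r0 + mu0
    changes = _fitch_changes(atree, space)
    # per-edge transition rate: changes spread over the tree length, split
    # between the K characters' two directions
    q0 = max(changes / (space.n_chars * tree_len), 1e-6)
    return lam0, mu0, q0


def _starts_for(spec: RateModelSpec, lam0: float, mu0: float, q0: float,
                config: FitConfig, rng: np.random.Generator
                ) -> list[np.ndarray]:
    def base(scale_mu: float, scale_q: float) -> np.ndarray:
        vals = []
        for name in spec.param_names:
            if name.startswith("lam"):
                vals.append(lam0)
            elif name.startswith("mu"):
                vals.append(mu0 * scale_mu)
            elif name == "r":
                vals.append(max(lam0 - mu0 * scale_mu, 1e-6))
            else:  # transition parameter
                vals.append(q0 * scale_q)
        return np.array(vals)

    starts = [base(1.0, 1.0), base(3.0, 5.0)]
    while len(starts) < config.n_starts:
        jitter = np.exp(rng.normal(0.0, 0.7, size=spec.n_params))
        starts.append(np.clip(base(1.0, 1.0) * jitter, RATE_LO, RATE_HI))
    starts = starts[:max(config.n_starts, 1)]
    starts += [np.asarray(s, dtype=float) for s in config.extra_starts]
    return [np.clip(s, RATE_LO, RATE_HI) for s in starts]


# ---------------------------------------------------------------------------
# Single fit
# ---------------------------------------------------------------------------

def fit_model(atree: AnnotatedTree, bipartition: Bipartition,
              spec: RateModelSpec, space: StateSpace,
              sampling: SamplingFractions, root: RootSpec,
              config: FitConfig | None = None) -> FitResult:
    """Maximise the SSE log-likelihood for one (bipartition, model) pair.

    Optimisation is on log-transformed rates with bounds
    ``[1e-9, 10]`` per Myr.  A non-converged optimiser result is retained and
    flagged rather than discarded.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    lam0, mu0, q0 = _heuristic_rates(atree, space)
    starts = _starts_for(spec, lam0, mu0, q0, config, rng)

    lo, hi = math.log(RATE_LO), math.log(RATE_HI)

    def objective(logp: np.ndarray) -> float:
        rs = build_rateset(bipartition, spec, np.exp(logp), space)
        ll = loglik(atree, rs, sampling, root,
                    condition_on_survival=config.condition_on_survival,
                    method="fast", max_step=config.max_step,
                    check_ultrametric=False)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    best = None
    converged = False
    for s in starts:
        res = minimize(objective, np.log(s), method="L-BFGS-B",
                       bounds=[(lo, hi)] * spec.n_params,
                       options={"maxiter": config.maxiter,
                                "ftol": config.ftol, "gtol": config.gtol})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    params = np.exp(best.x)
    rs = build_rateset(bipartition, spec, params, space)
    lnL = -float(best.fun)
    if best.fun >= 1e10:
        lnL = -math.inf
    return FitResult(
        mask=bipartition.mask,
        transition_model=spec.transition.name,
        diversification_model=spec.diversification.name,
        param_names=spec.param_names,
        params=params,
        lnL=lnL,
        k=spec.n_params,
        converged=converged,
        set_rates=spec.expand(params),
        rateset=rs,
    )


def fit_grid(atree: AnnotatedTree, space: StateSpace,
             sampling: SamplingFractions, root: RootSpec,
             bipartitions: Sequence[Bipartition] | None = None,
             grid: Sequence[RateModelSpec] | None = None,
             config: FitConfig | None = None) -> list[FitResult]:
    """Fit every (viable bipartition, model) pair, in deterministic order."""
    grid = list(grid) if grid is not None else model_grid()
    if bipartitions is None:
        bipartitions = filter_viable(enumerate_bipartitions(space),
                                     atree.observed_states(), space)
    log.info("fitting %d bipartitions x %d models = %d fits",
             len(bipartitions), len(grid), len(bipartitions) * len(grid))
    fits = []
    for bp in bipartitions:
        for spec in grid:
            try:
                fit = fit_model(atree, bp, spec, space, sampling, root, config)
            except Exception as exc:  # keep going; record the failure
                log.warning("fit failed for %s / %s: %s", bp.mask,
                            spec.name, exc)
                continue
            if not fit.converged:
                log.warning("optimiser did not converge for %s / %s",
                            bp.mask, spec.name)
            fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# AIC machinery
# ---------------------------------------------------------------------------

def akaike_weights(aic: Sequence[float]) -> np.ndarray:
    """``w_m = exp(-(AIC_m - min AIC)/2)``, normalised to sum to one."""
    aic = np.asarray(aic, dtype=float)
    if aic.size == 0 or not np.isfinite(aic).any():
        raise ValueError("need at least one finite AIC value")
    delta = aic - np.nanmin(aic[np.isfinite(aic)])
    w = np.where(np.isfinite(delta), np.exp(-0.5 * delta), 0.0)
    return w / w.sum()


def model_average(fits: Sequence[FitResult],
                  weights: Sequence[float] | None = None) -> RateSet:
    """Akaike-weighted elementwise mean of the expanded per-state rates.

    Averaging happens after each model is expanded to full per-state lambda,
    mu and per-edge Q, across all supplied fits (no top-N truncation).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to average")
    if any(f.rateset is None for f in fits):
        raise ValueError("all fits must carry an expanded rateset")
    if weights is None:
        w = akaike_weights([f.aic for f in fits])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(fits),):
            raise ValueError("weights length does not match fits")
        w = w / w.sum()
    lam = sum(wi * f.rateset.lam for wi, f in zip(w, fits))
    mu = sum(wi * f.rateset.mu for wi, f in zip(w, fits))
    Q = sum(wi * f.rateset.Q for wi, f in zip(w, fits))
    return RateSet(lam, mu, Q)


_TABLE_COLS = ["akaike_weight", "cumulative_weight", "focal",
               "diversification", "r_F", "r_N", "transitions",
               "q_FN", "q_NF", "q_NN", "q_FF", "lnL", "k", "AIC"]


def rank_table(fits: Sequence[FitResult], top_n: int | None = 10
               ) -> pd.DataFrame:
    """Ranked model table: Akaike weight, cumulative weight and set-level
    rates, sorted by weight descending (ties broken by mask then model ids)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    w = akaike_weights([f.aic for f in fits])
    rows = []
    for wi, f in zip(w, fits):
        rows.append({
            "akaike_weight": wi,
            "focal": f.mask,
            "diversification": f.diversification_model,
            "r_F": f.r_F,
            "r_N": f.r_N,
            "transitions": f.transition_model,
            "q_FN": f.set_rates["q_FN"],
            "q_NF": f.set_rates["q_NF"],
            "q_NN": f.set_rates["q_NN"],
            "q_FF": f.set_rates["q_FF"],
            "lnL": f.lnL,
            "k": f.k,
            "AIC": f.aic,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["akaike_weight", "focal", "transitions", "diversification"],
        ascending=[False, True, True, True], kind="mergesort",
    ).reset_index(drop=True)
    df.insert(1, "cumulative_weight", df["akaike_weight"].cumsum())
    if top_n is not None:
        df = df.head(top_n)
    return df[_TABLE_COLS]


def write_model_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Per-fit JSON records (rateset reconstructible from mask + model + params)
# ---------------------------------------------------------------------------

def fits_to_json(fits: Sequence[FitResult], path: str) -> None:
    recs = []
    for f in fits:
        recs.append({
            "mask": f.mask,
            "transition_model": f.transition_model,
            "diversification_model": f.diversification_model,
            "param_names": list(f.param_names),
            "params": [float(p) for p in f.params],
            "lnL": f.lnL if np.isfinite(f.lnL) else None,
            "k": f.k,
            "AIC": f.aic if np.isfinite(f.aic) else None,
            "converged": f.converged,
            "set_rates": {k: float(v) for k, v in f.set_rates.items()},
        })
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)


def fits_from_json(path: str, space: StateSpace) -> list[FitResult]:
    from .trait_space import DIVERSIFICATION_MODELS, TRANSITION_MODELS
    with open(path) as fh:
        recs = json.load(fh)
    fits = []
    for r in recs:
        spec = RateModelSpec(TRANSITION_MODELS[r["transition_model"]],
                             DIVERSIFICATION_MODELS[r["diversification_model"]])
        bp = Bipartition(r["mask"])
        params = np.asarray(r["params"], dtype=float)
        fits.append(FitResult(
            mask=r["mask"],
            transition_model=r["transition_model"],
            diversification_model=r["diversification_model"],
            param_names=tuple(r["param_names"]),
            params=params,
            lnL=r["lnL"] if r["lnL"] is not None else -math.inf,
            k=r["k"],
            converged=r["converged"],
            set_rates=r["set_rates"],
            rateset=build_rateset(bp, spec, params, space),
        ))
    return fits
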