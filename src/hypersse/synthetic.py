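"""Study-shaped synthetic inputs: simulated trees with six binary characters,
and the stratified taxon-sampling design used to assemble such datasets.

The default generating process mirrors the angiosperm analysis that motivates
this package: a single lineage evolving for 136 Myr (the approximate crown
age of angiosperms) over the 64-state hypercube of six binary floral
characters, where the focal combination set ``0*11**`` (corolla present,
bilateral symmetry, few stamens) has net diversification roughly 0.064/Myr
against 0.038/Myr elsewhere, and every per-edge transition rate is a small
0.001/Myr.  The resulting tree is pruned uniformly at random to 464 extant
species.  Because transitions are rare relative to diversification, datasets
generated this way start far from the stationary state frequencies — the
non-equilibrium signature the analysis pipeline is designed to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import AnnotatedTree
from .simulate import SimConfig, prune_subsample, simulate_tree
from .trait_space import (Bipartition, DIVERSIFICATION_MODELS, RateModelSpec,
                          RateSet, StateSpace, TRANSITION_MODELS,
                          build_rateset)

__all__ = [
    "SyntheticDatasetConfig",
    "default_rateset",
    "generate_dataset",
    "stratified_sample",
    "synthetic_family_table",
]

log = logging.getLogger(__name__)


@dataclass
class SyntheticDatasetConfig:
    """Generating conditions for a synthetic dataset.

    Defaults emulate the study design: 464 tips, 136 Myr crown age, focal
    mask ``0*11**`` with elevated net diversification (0.064 vs 0.038 per
    Myr), per-edge transition rate 0.001/Myr, root in the all-ancestral
    combination.
    """

    n_tips: int = 464
    crown_age: float = 136.0
    n_chars: int = 6
    focal_mask: str = "0*11**"
    lam_F: float = 0.070
    mu_F: float = 0.006
    lam_N: float = 0.042
    mu_N: float = 0.004
    q: float = 0.001
    root_state: int = 0
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if min(self.lam_F, self.mu_F, self.lam_N, self.mu_N, self.q) < 0:
            raise ValueError("generating rates must be non-negative")
        if len(self.focal_mask) != self.n_chars:
            raise ValueError("focal mask length must equal n_chars")

    @property
    def space(self) -> StateSpace:
        return StateSpace(self.n_chars)


def default_rateset(config: SyntheticDatasetConfig | None = None) -> RateSet:
    """Expand the generating conditions to a full per-state rate set."""
    config = config or SyntheticDatasetConfig()
    spec = RateModelSpec(TRANSITION_MODELS["one-rate"],
                         DIVERSIFICATION_MODELS["free"])
    params = [config.lam_F, config.lam_N, config.mu_F, config.mu_N, config.q]
    return build_rateset(Bipartition(config.focal_mask), spec, params,
                         config.space)


def generate_dataset(config: SyntheticDatasetConfig | None = None
                     ) -> tuple[AnnotatedTree, pd.DataFrame]:
    """Simulate a tree, prune to ``n_tips`` extant species, decode characters.

    Replicate substreams are drawn from the master seed until a simulation
    survives with at least ``n_tips`` extant lineages (bounded by
    ``max_retries``); the pruned ultrametric tree and the 0/1 character
    matrix are returned.
    """
    from .io import states_to_matrix  # local import to avoid a cycle

    config = config or SyntheticDatasetConfig()
    rateset = default_rateset(config)
    ss = np.random.SeedSequence(config.seed)
    for attempt, child in enumerate(ss.spawn(config.max_retries)):
        rng = np.random.default_rng(child)
        sim = SimConfig(rateset=rateset, duration=config.crown_age,
                        root_state=config.root_state, seed=0)
        atree = simulate_tree(sim, rng)
        extinct = set(atree.metadata.get("extinct_labels", []))
        n_extant = len(atree.tip_states) - len(extinct)
        if atree.metadata.get("all_extinct") or n_extant < config.n_tips:
            continue
        pruned = prune_subsample(atree, config.n_tips, rng)
        pruned.metadata["generating_config"] = config
        pruned.metadata["attempts"] = attempt + 1
        chars = states_to_matrix(pruned.tip_states, config.space)
        log.info("synthetic dataset after %d attempt(s): %d of %d extant tips",
                 attempt + 1, config.n_tips, n_extant)
        return pruned, chars
    raise RuntimeError(
        f"no simulation reached {config.n_tips} extant tips in "
        f"{config.max_retries} attempts")


# ---------------------------------------------------------------------------
# Stratified sampling design
# ---------------------------------------------------------------------------

def stratified_sample(family_table: pd.DataFrame, total_n: int,
                      rng: np.random.Generator) -> pd.Series:
    """Per-family sample counts proportional to family species richness.

    Each family's expected count is ``total_n * richness / total_richness``.
    The integer part is allocated deterministically and the fractional part
    by dynamic rounding — one extra species with probability equal to the
    fraction — so the expectation of the returned counts equals the exact
    fractional expectation (a family holding 1% of the clade contributes
    exactly 1% of a 500-species design in expectation, i.e. 5 species).
    """
    if total_n < 1:
        raise ValueError("total_n must be >= 1")
    rich = family_table["richness"].to_numpy(dtype=float)
    total_rich = rich.sum()
    if total_n > total_rich:
        raise ValueError("cannot sample more species than exist")
    expected = total_n * rich / total_rich
    base = np.floor(expected)
    frac = expected - base
    extra = rng.uniform(size=len(frac)) < frac
    counts = (base + extra).astype(int)
    return pd.Series(counts, index=family_table["family"].to_numpy(),
                     name="n_sampled")


def synthetic_family_table(n_families: int = 134,
                           total_richness: int = 250_000,
                           seed: int = 0,
                           theta: float = 0.98) -> pd.DataFrame:
    """A log-series-like family richness table for exercising the sampler.

    Richness values are drawn from a logarithmic-series distribution (the
    classic fit to taxonomic abundance data) and rescaled so the clade totals
    ``total_richness`` species.
    """
    rng = np.random.default_rng(seed)
    raw = rng.logseries(theta, size=n_families).astype(float)
    scaled = np.maximum(1, np.round(raw * total_richness / raw.sum())).astype(int)
    # adjust the largest family so the total is exact
    diff = total_richness - scaled.sum()
    scaled[np.argmax(scaled)] += diff
    if scaled.min() < 1:
        raise ValueError("richness rescaling produced an empty family")
    return pd.DataFrame({
        "family": [f"fam{i + 1}" for i in range(n_families)],
        "richness": scaled,
    })
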