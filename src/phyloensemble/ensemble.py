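"""Chained MCMC over a sample of trees.

Phylogenetic uncertainty is integrated over by running the mixed-model
sampler across an ordered sample of trees: the chain state at the last
iteration under tree i seeds the chain under tree i+1, draws retained under
each tree are pooled, and draws from the first ``tree_burn_in`` trees are
discarded. The classic presets retain exactly one draw per tree (iterations
1,000 / burn-in 999 and 10,000 / 9,999, thinning 1) with 1,500 trees of which
the first 500 are burn-in, yielding 1,000 pooled draws.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec, PriorSpec
from .model import MCMCState, PosteriorSamples, _Sampler
from .trees import TreeEnsemble, augment_with_replicates, phylo_covariance

__all__ = ["EnsembleSettings", "run_over_trees", "gelman_rubin"]

log = logging.getLogger("phyloensemble.ensemble")


@dataclass
class EnsembleSettings:
    """Iteration schedule for the chained multi-tree procedure."""

    iterations_per_tree: int = 1000
    burn_in_per_tree: int = 999
    thin: int = 1
    tree_burn_in: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.burn_in_per_tree >= self.iterations_per_tree:
            raise ValueError("burn_in_per_tree must be < iterations_per_tree")
        if self.tree_burn_in < 0:
            raise ValueError("tree_burn_in must be >= 0")

    @classmethod
    def paper_experiment(cls, seed: int = 0) -> "EnsembleSettings":
        """1,000 iterations per tree, burn-in 999, thin 1, 500 trees burned."""
        return cls(1000, 999, 1, 500, seed)

    @classmethod
    def paper_lake(cls, seed: int = 0) -> "EnsembleSettings":
        """10,000 iterations per tree, burn-in 9,999, thin 1, 500 trees burned."""
        return cls(10000, 9999, 1, 500, seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "EnsembleSettings":
        """A light schedule for smoke runs and small ensembles."""
        return cls(iterations_per_tree=60, burn_in_per_tree=40, thin=2,
                   tree_burn_in=2, seed=seed)

    def retained_per_tree(self) -> int:
        return (self.iterations_per_tree - self.burn_in_per_tree - 1) // self.thin + 1


class EnsembleFitError(RuntimeError):
    """A per-tree fit failure, carrying the tree index."""

    def __init__(self, tree_index: int, cause: Exception):
        super().__init__(f"fit failed at tree {tree_index}: {cause}")
        self.tree_index = tree_index
        self.cause = cause


def run_over_trees(
    data: pd.DataFrame,
    spec: ModelSpec,
    ensemble: TreeEnsemble,
    priors: PriorSpec | None = None,
    settings: EnsembleSettings | None = None,
    augmentation: dict | None = None,
    tip_length: float | None = None,
    fix_residual: bool = False,
    return_state: bool = False,
    state_callback=None,
):
    """Run the chained multi-tree procedure and pool the retained draws.

    For each tree the phylogenetic covariance (as a correlation matrix, after
    optional replicate augmentation) is rebuilt, the sampler is run starting
    from the previous tree's final state, and retained draws are tagged with
    the tree index. Draws from trees with index < ``tree_burn_in`` are
    discarded, so the pooled draw count is
    ``(len(ensemble) - tree_burn_in) * retained_per_tree``.

    ``augmentation`` is the species->strain->observation mapping handed to
    :func:`augment_with_replicates`; without it the tree's tips must already
    match the phylo random-term group levels. ``state_callback(i, state)`` is
    invoked with each tree's final state (used by chaining-contract tests and
    structured logging).
    """
    settings = settings or EnsembleSettings()
    if settings.tree_burn_in >= len(ensemble):
        raise ValueError("tree_burn_in must be smaller than the ensemble size")
    priors = priors or PriorSpec()
    rng = np.random.default_rng(settings.seed)
    phylo_keys = sorted(
        {t.covariance for t in spec.random_terms if t.covariance != "identity"}
    )
    state: MCMCState | None = None
    parts: list[PosteriorSamples] = []
    for i, tree in enumerate(ensemble):
        t_start = time.perf_counter()
        try:
            if augmentation is not None:
                tree_i = augment_with_replicates(tree, augmentation, tip_length=tip_length)
            else:
                tree_i = tree
            cov = phylo_covariance(tree_i, as_correlation=True)
            covariances = {k: cov for k in phylo_keys}
            sampler = _Sampler(data, spec, covariances, priors, fix_residual=fix_residual)
            samples, state = sampler.run(
                settings.iterations_per_tree,
                settings.burn_in_per_tree,
                settings.thin,
                rng,
                state=state,
                tree_index=i,
                adapt=(i == 0),  # proposal scale frozen after the first tree
            )
        except Exception as exc:
            raise EnsembleFitError(i, exc) from exc
        if state_callback is not None:
            state_callback(i, state)
        log.info(
            "tree %d: %.3fs, acceptance=%s",
            i,
            time.perf_counter() - t_start,
            f"{samples.extras['acceptance']:.3f}"
            if samples.extras.get("acceptance") is not None
            else "n/a",
        )
        if i >= settings.tree_burn_in:
            parts.append(samples)
    pooled = PosteriorSamples.concatenate(parts)
    pooled.extras["seed"] = settings.seed
    if return_state:
        return pooled, state
    return pooled


def gelman_rubin(chains: list[PosteriorSamples]) -> pd.DataFrame:
    """Classic potential scale-reduction factor (PSRF) per parameter.

    Requires >= 2 chains of equal length (>= 10 draws). PSRF values below 1.1
    are the conventional convergence criterion; the returned frame flags
    parameters at or above it.
    """
    if len(chains) < 2:
        raise ValueError("gelman_rubin requires at least two chains")
    names = chains[0].names
    n = chains[0].n_draws
    for c in chains[1:]:
        if c.names != names:
            raise ValueError("chains have different parameters")
        if c.n_draws != n:
            raise ValueError("chains have different lengths")
    if n < 10:
        raise ValueError("chains must have >= 10 draws")
    draws = np.stack([c.draws for c in chains])  # (m, n, p)
    m = draws.shape[0]
    chain_means = draws.mean(axis=1)  # (m, p)
    chain_vars = draws.var(axis=1, ddof=1)  # (m, p)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(var_hat / W)
    psrf = np.where(W == 0, 1.0, psrf)
    return pd.DataFrame({"parameter": names, "psrf": psrf, "converged": psrf < 1.1})
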