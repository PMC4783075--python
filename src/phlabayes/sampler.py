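"""Metropolis-Hastings sampling of the immunogenicity posterior.

The unnormalised log target is cohort log-likelihood plus log prior
density.  The proposal is a full-vector Gaussian random walk reflected at
0 and 1, which is symmetric on the hypercube, so the acceptance ratio is
the plain target ratio.  Several independent chains (one per peptide of
the same cohort) can be advanced in lock-step as a batch: the per-iteration
cost is a single (N x m) @ (m x K) product, which is what makes the
simulation study's thousands of chains affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CohortTable, RunConfig, cohort_log_likelihood_batch
from .priors import PriorSpec, log_prior_density_batch

__all__ = ["Chain", "propose", "run_chain", "run_chains"]


@dataclass(frozen=True)
class Chain:
    """Post-burn-in posterior sample for one peptide."""

    samples: np.ndarray  # (S, m)
    acceptance_rate: float
    seed: int
    config: RunConfig
    allele_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be an S x m matrix")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.samples.shape[1]


def reflect_unit(x: np.ndarray) -> np.ndarray:
    """Fold arbitrary reals back into [0, 1] by reflection at both walls."""
    return 1.0 - np.abs(1.0 - np.mod(x, 2.0))


def propose(current: np.ndarray, step: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric reflected-Gaussian random-walk proposal."""
    current = np.asarray(current, dtype=float)
    if step < 0:
        raise ValueError("step must be non-negative")
    return reflect_unit(current + rng.normal(0.0, step, size=current.shape) if step > 0 else current)


def _mh_loop(
    copies: np.ndarray,
    outcomes: list[np.ndarray],
    obs_masks: list[np.ndarray],
    prior: PriorSpec,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance K independent chains; returns (kept samples (S,K,m), acc (K,))."""
    K = len(outcomes)
    m = copies.shape[1]
    eps = config.likelihood_clip_epsilon

    def log_target(E: np.ndarray) -> np.ndarray:
        lp = log_prior_density_batch(prior, E, eps)
        for k in range(K):
            lp[k] += cohort_log_likelihood_batch(
                copies[obs_masks[k]], outcomes[k], E[k][None, :], eps
            )[0]
        return lp

    # Fast path: all chains share the full copy matrix (no missing data),
    # so the likelihood of all K chains is one matrix product.
    shared = all(mask.all() for mask in obs_masks)
    if shared and K > 0:
        outcome_mat = np.stack(outcomes, axis=1) if copies.shape[0] else np.zeros((0, K), bool)
        log_eps = np.log(eps)

        def log_target(E: np.ndarray) -> np.ndarray:  # noqa: F811
            lp = log_prior_density_batch(prior, E, eps)
            if copies.shape[0]:
                with np.errstate(divide="ignore", invalid="ignore"):
                    logq = copies @ np.log1p(-E).T  # (N, K)
                    neg = np.maximum(logq, log_eps)
                    pos = np.minimum(np.log(np.maximum(-np.expm1(logq), eps)), 0.0)
                lp += np.where(outcome_mat, pos, neg).sum(axis=0)
            return lp

    current = prior.sample(rng, size=K)  # (K, m)
    cur_lp = log_target(current)
    if not np.all(np.isfinite(cur_lp)):
        raise RuntimeError("non-finite log target at initialization")

    n_keep = config.n_kept
    n_discard = config.chain_length - n_keep
    kept = np.empty((n_keep, K, m))
    accepts = np.zeros(K, dtype=np.int64)
    step = config.proposal_step
    for it in range(config.chain_length):
        prop = reflect_unit(current + rng.normal(0.0, step, size=(K, m)))
        prop_lp = log_target(prop)
        log_u = np.log(rng.random(K))
        accept = log_u < (prop_lp - cur_lp)
        if accept.any():
            current = np.where(accept[:, None], prop, current)
            cur_lp = np.where(accept, prop_lp, cur_lp)
            accepts += accept
        if it >= n_discard:
            kept[it - n_discard] = current
    return kept, accepts / config.chain_length


def run_chains(
    cohort: CohortTable,
    peptides: list[str],
    prior: PriorSpec,
    config: RunConfig,
) -> dict[str, Chain]:
    """Sample the posterior for several peptides of one cohort at once.

    Chains are statistically independent; batching only shares the
    iteration loop.  Deterministic under (inputs, config.seed).
    """
    if config.chain_length < 1_000:
        raise ValueError("chain_length must be at least 1,000")
    if tuple(prior.allele_names) != tuple(cohort.allele_names):
        raise ValueError("prior alleles do not match cohort alleles")
    outcomes, masks = [], []
    for pep in peptides:
        if cohort.n_subjects == 0:
            masks.append(np.zeros(0, dtype=bool))
            outcomes.append(np.zeros(0, dtype=bool))
            continue
        resp = cohort.response_vector(pep)
        mask = resp.notna().to_numpy()
        masks.append(mask)
        outcomes.append(resp[mask].to_numpy(dtype=bool))
    rng = np.random.Generator(np.random.PCG64(config.seed))
    kept, acc = _mh_loop(cohort.copy_matrix, outcomes, masks, prior, config, rng)
    return {
        pep: Chain(
            samples=kept[:, k, :].copy(),
            acceptance_rate=float(acc[k]),
            seed=config.seed,
            config=config,
            allele_names=tuple(cohort.allele_names),
        )
        for k, pep in enumerate(peptides)
    }


def run_chain(
    cohort: CohortTable,
    peptide: str,
    prior: PriorSpec,
    config: RunConfig,
) -> Chain:
    """Sample the posterior P(E | data) for a single peptide."""
    return run_chains(cohort, [peptide], prior, config)[peptide]
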