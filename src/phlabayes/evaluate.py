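"""ROC/AUC validation against ground-truth immunogenicity labels.

Posterior modes of informative peptide:HLA combinations are scored against
Boolean truth labels (simulated immunogenicities over a cut-off, or any
externally supplied labels such as single-HLA transgenic readouts).  A
naive counting comparator — the fraction of an allele's carriers with a
positive ELISpot — is provided as the baseline the Bayesian model must
beat when linkage between loci confounds simple counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .model import CohortTable, RunConfig
from .priors import PriorSpec
from .sampler import run_chains
from .summary import kl_threshold, summarize

__all__ = [
    "roc_auc",
    "counting_baseline",
    "sweep_auc",
    "SweepResult",
    "DEFAULT_SIZES",
    "DEFAULT_CUTOFFS",
]

DEFAULT_SIZES = (10, 30, 50, 70, 100, 150, 200)
DEFAULT_CUTOFFS = (0.1, 0.2, 0.3, 0.4, 0.5)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUC of *scores* against Boolean *labels*.

    Thresholds sweep the distinct scores; tied scores are grouped, which
    makes the trapezoidal area equal the normalised Mann-Whitney U
    statistic (ties counting one half).  Raises if only one class is
    present rather than returning NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-d arrays")
    if labels.all() or (~labels).all():
        raise ValueError("AUC undefined: both a positive and a negative label are required")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def counting_baseline(cohort: CohortTable, peptide: str) -> pd.Series:
    """Per-allele fraction of carriers with a positive ELISpot.

    Alleles with no carriers are excluded (the fraction is undefined).
    """
    counts = cohort.carrier_counts(peptide)
    counts = counts[counts["n_carriers"] > 0]
    return pd.Series(
        (counts["n_carriers_positive"] / counts["n_carriers"]).to_numpy(),
        index=counts["allele"].to_numpy(),
        name="positive_fraction",
    )


@dataclass(frozen=True)
class SweepResult:
    """Simulation-study output.

    ``grid``: long table (n, cutoff, replicate, auc, n_scored) with NaN auc
    where a replicate had a single truth class after filtering (recorded,
    never silently dropped).  ``cells``: mean AUC per (n, cutoff) over the
    defined replicates.  ``records``: per-peptide detail (n, replicate,
    peptide, success_rate, auc, ...) for stratified analyses.
    """

    grid: pd.DataFrame
    records: pd.DataFrame

    @property
    def cells(self) -> pd.DataFrame:
        return (
            self.grid.groupby(["n", "cutoff"], as_index=False)["auc"]
            .mean()
            .rename(columns={"auc": "mean_auc"})
        )


def sweep_auc(
    genotype_pool: CohortTable,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    replicates: int = 20,
    seed: int = 0,
    n_peptides: int = 17,
    chain_length: int = 20_000,
    apply_kl_filter: bool = True,
    proposal_step: float = 0.05,
) -> SweepResult:
    """Full synthetic validation: simulate, infer, score, per grid cell.

    For every (cohort size, replicate): resample a cohort, simulate
    *n_peptides* peptides, run one Metropolis-Hastings chain per peptide,
    keep informative peptide:HLA pairs (KL filter, unless disabled), then
    for every cut-off compute the AUC of posterior modes against the
    truth labels, pooling pairs across peptides.  The cut-off only alters
    the labels, so all cut-offs share each replicate's chains.
    Deterministic under *seed*.
    """
    from .simulate import simulate_study  # local import to avoid a cycle

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(replicates * len(sizes))
    prior = PriorSpec.uniform(list(genotype_pool.allele_names))
    threshold = kl_threshold() if apply_kl_filter else 0.0
    grid_rows, record_rows = [], []
    idx = 0
    for rep in range(replicates):
        for n in sizes:
            child = rep_seeds[idx]
            idx += 1
            chain_seed = int(child.generate_state(1)[0] % (2**31))
            cohort, truth = simulate_study(genotype_pool, n, n_peptides, seed=child)
            config = RunConfig(
                chain_length=chain_length, seed=chain_seed, proposal_step=proposal_step
            )
            peptides = cohort.peptides
            chains = run_chains(cohort, peptides, prior, config)
            truth_idx = truth.set_index(["peptide", "allele"])["e_true"]
            scores, e_values = [], []
            for pep in peptides:
                summaries = summarize(chains[pep], cohort, pep, config)
                resp = cohort.response_vector(pep).dropna()
                success_rate = float(resp.mean()) if len(resp) else np.nan
                pep_scores, pep_e = [], []
                for s in summaries:
                    if s.kl_vs_uniform < threshold:
                        continue
                    e_true = float(truth_idx.loc[(pep, s.allele)])
                    pep_scores.append(s.mode)
                    pep_e.append(e_true)
                    scores.append(s.mode)
                    e_values.append(e_true)
                record_rows.append(
                    {
                        "n": n,
                        "replicate": rep,
                        "peptide": pep,
                        "success_rate": success_rate,
                        "n_informative": len(pep_scores),
                        "scores": np.array(pep_scores),
                        "e_true": np.array(pep_e),
                    }
                )
            scores = np.array(scores)
            e_values = np.array(e_values)
            for cutoff in cutoffs:
                labels = e_values >= cutoff
                if len(scores) == 0 or labels.all() or (~labels).all():
                    auc = np.nan  # single-class cell: undefined, kept visible
                else:
                    _, auc = roc_auc(scores, labels)
                grid_rows.append(
                    {
                        "n": n,
                        "cutoff": cutoff,
                        "replicate": rep,
                        "auc": auc,
                        "n_scored": len(scores),
                    }
                )
    return SweepResult(grid=pd.DataFrame(grid_rows), records=pd.DataFrame(record_rows))
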