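"""Marginal posterior summaries and the KL informativeness filter.

Each allele's marginal posterior is summarised by its histogram mode (the
headline immunogenicity estimate), mean and median.  A marginal that stays
close to flat carries too little information to act on; the filter keeps
only alleles whose Kullback-Leibler divergence from Uniform(0,1) exceeds
that of Beta(2,1) — the posterior of a coin's bias after a single toss —
i.e. marginals that say more than one observation's worth.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .model import CohortTable, RunConfig
from .sampler import Chain

__all__ = [
    "MarginalSummary",
    "marginal_mode",
    "kl_vs_uniform",
    "kl_threshold",
    "summarize",
    "summaries_to_frame",
]

SUMMARY_COLUMNS = [
    "allele",
    "posterior_mode",
    "posterior_mean",
    "posterior_median",
    "kl",
    "informative",
    "n_carriers",
    "n_carriers_positive",
]


@dataclass(frozen=True)
class MarginalSummary:
    allele: str
    mode: float
    mean: float
    median: float
    kl_vs_uniform: float
    informative: bool
    n_carriers: int
    n_carriers_positive: int


def _histogram(samples: np.ndarray, bins: int) -> np.ndarray:
    counts, _ = np.histogram(samples, bins=bins, range=(0.0, 1.0))
    return counts


def marginal_mode(chain: Chain | np.ndarray, allele_index: int = 0, bins: int = 100) -> float:
    """Histogram mode of one marginal: midpoint of the fullest of *bins*
    equal-width bins on [0, 1]; ties go to the lower bin."""
    samples = chain.samples[:, allele_index] if isinstance(chain, Chain) else np.asarray(chain)
    if samples.size == 0:
        raise ValueError("cannot take the mode of an empty chain")
    counts = _histogram(samples, bins)
    b = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return (b + 0.5) / bins


def kl_vs_uniform(chain: Chain | np.ndarray, allele_index: int = 0, bins: int = 100) -> float:
    """Plug-in histogram estimate of D_KL(marginal || Uniform(0,1)).

    With bin masses p_b this is sum_b p_b log(p_b * bins); empty bins
    contribute 0 (the 0 log 0 convention).  Non-negative up to float error.
    """
    samples = chain.samples[:, allele_index] if isinstance(chain, Chain) else np.asarray(chain)
    if samples.size == 0:
        raise ValueError("cannot estimate KL from an empty chain")
    counts = _histogram(samples, bins)
    p = counts / counts.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * bins)))


def kl_threshold() -> float:
    """Informativeness cut-off: D_KL(Beta(2,1) || Uniform(0,1)) = ln 2 - 1/2.

    Beta(2,1) is the posterior of a Bernoulli parameter after one
    observation under a uniform prior, so the filter demands more
    information than a single coin toss.  By the x -> 1-x symmetry of the
    divergence to the uniform, Beta(1,2) gives the same value.  Users may
    pass their own threshold wherever this default is consumed.
    """
    return math.log(2.0) - 0.5


def summarize(
    chain: Chain,
    cohort: CohortTable,
    peptide: str,
    config: RunConfig | None = None,
    threshold: float | None = None,
) -> list[MarginalSummary]:
    """Per-allele marginal summaries with carrier counts for *peptide*.

    The mode and the KL estimate share the same ``config.density_bins``-bin
    histogram so the informative flag and the reported mode are consistent.
    """
    config = config or chain.config
    bins = config.density_bins
    if threshold is None:
        threshold = kl_threshold()
    counts = cohort.carrier_counts(peptide).set_index("allele")
    out = []
    for j, allele in enumerate(cohort.allele_names):
        samples = chain.samples[:, j]
        kl = kl_vs_uniform(samples, bins=bins)
        out.append(
            MarginalSummary(
                allele=allele,
                mode=marginal_mode(samples, bins=bins),
                mean=float(samples.mean()),
                median=float(np.median(samples)),
                kl_vs_uniform=kl,
                informative=bool(kl >= threshold),
                n_carriers=int(counts.loc[allele, "n_carriers"]),
                n_carriers_positive=int(counts.loc[allele, "n_carriers_positive"]),
            )
        )
    return out


def summaries_to_frame(summaries: list[MarginalSummary]) -> pd.DataFrame:
    """Summary table in the output CSV column layout."""
    return pd.DataFrame(
        {
            "allele": [s.allele for s in summaries],
            "posterior_mode": [s.mode for s in summaries],
            "posterior_mean": [s.mean for s in summaries],
            "posterior_median": [s.median for s in summaries],
            "kl": [s.kl_vs_uniform for s in summaries],
            "informative": [s.informative for s in summaries],
            "n_carriers": [s.n_carriers for s in summaries],
            "n_carriers_positive": [s.n_carriers_positive for s in summaries],
        },
        columns=SUMMARY_COLUMNS,
    )
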