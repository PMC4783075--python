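"""Ranking and winner-takes-all attribution of positive ELISpots.

Alleles are ranked by descending posterior mode.  Each subject with a
positive ELISpot is attributed to the single highest-ranked allele they
carry ("explained"): an allele with many positive carriers but no explained
positives owes its carriers' responses to higher-ranked alleles they also
carry, which is exactly the confounding-by-linkage pattern the joint model
is there to resolve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CohortTable
from .summary import MarginalSummary

__all__ = ["rank_hlas", "explain_positives"]

ATTRIBUTION_COLUMNS = [
    "allele",
    "rank",
    "posterior_mode",
    "informative",
    "n_carriers",
    "n_carriers_positive",
    "n_explained",
]


def rank_hlas(summaries: list[MarginalSummary]) -> list[str]:
    """Alleles ordered by descending posterior mode.

    Ties break toward the allele with more carriers, then lexicographically,
    so the ranking (and hence attribution) is deterministic.
    """
    return [
        s.allele
        for s in sorted(summaries, key=lambda s: (-s.mode, -s.n_carriers, s.allele))
    ]


def explain_positives(
    cohort: CohortTable,
    peptide: str,
    ranking: list[str],
    summaries: list[MarginalSummary],
) -> pd.DataFrame:
    """Attribution table: one row per allele in rank order.

    ``n_explained`` counts the positive-ELISpot subjects for whom this
    allele is the highest-ranked among those they carry; every positive
    subject is attributed to exactly one allele, so the column sums to the
    number of positives.
    """
    if sorted(ranking) != sorted(cohort.allele_names):
        raise ValueError("ranking must cover exactly the cohort's alleles")
    by_allele = {s.allele: s for s in summaries}
    rank_of = {allele: r for r, allele in enumerate(ranking)}
    col_rank = np.array([rank_of[a] for a in cohort.allele_names])
    counts = cohort.carrier_counts(peptide).set_index("allele")

    copies, outcome = cohort.observed(peptide)
    explained = {allele: 0 for allele in ranking}
    for row in copies[outcome]:
        carried = np.flatnonzero(row >= 1)
        winner = carried[np.argmin(col_rank[carried])]
        explained[cohort.allele_names[winner]] += 1

    records = []
    for r, allele in enumerate(ranking, start=1):
        s = by_allele[allele]
        records.append(
            {
                "allele": allele,
                "rank": r,
                "posterior_mode": s.mode,
                "informative": s.informative,
                # counts recomputed from the cohort so the table is
                # internally consistent whatever the summaries carry
                "n_carriers": int(counts.loc[allele, "n_carriers"]),
                "n_carriers_positive": int(counts.loc[allele, "n_carriers_positive"]),
                "n_explained": explained[allele],
            }
        )
    return pd.DataFrame(records, columns=ATTRIBUTION_COLUMNS)
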