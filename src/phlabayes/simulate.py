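"""Synthetic cohorts with known ground-truth immunogenicities.

The study design being emulated: HLA class II haplotypes are resampled
with replacement from a genotype pool; each peptide:HLA pair receives an
immunogenicity drawn uniformly on [0, 0.55]; each subject's ELISpot
outcome is Bernoulli with success probability
``1 - prod_j (1 - E_j) ** n_ij`` — a positive is drawn when the uniform
random number falls below that probability.  A pair counts as truly
immunogenic when its immunogenicity reaches the chosen cut-off
(boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CohortTable

__all__ = [
    "SimulationGroundTruth",
    "genotype_pool_from_frequencies",
    "resample_cohort",
    "draw_immunogenicities",
    "simulate_elispot",
    "simulate_study",
    "odds_ratios",
]

IMMUNOGENICITY_UPPER = 0.55
DEFAULT_N_PEPTIDES = 17


@dataclass(frozen=True)
class SimulationGroundTruth:
    """True immunogenicities and the cut-off-derived Boolean labels."""

    allele_names: tuple[str, ...]
    e_true: np.ndarray
    immunogenicity_cutoff: float

    def __post_init__(self) -> None:
        if len(self.allele_names) != len(self.e_true):
            raise ValueError("one immunogenicity per allele required")

    @property
    def labels(self) -> np.ndarray:
        # boundary inclusive: E_true exactly at the cut-off is immunogenic
        return self.e_true >= self.immunogenicity_cutoff

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele": list(self.allele_names),
                "e_true": self.e_true,
                "label": self.labels,
            }
        )


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(seed))


def genotype_pool_from_frequencies(
    frequencies: pd.DataFrame,
    n_subjects: int,
    seed: int | np.random.Generator = 0,
) -> CohortTable:
    """Build a genotype pool by drawing two alleles per locus per subject.

    *frequencies* needs columns (locus, allele, frequency); frequencies are
    normalised within each locus.  The two chromosomes of a locus are drawn
    independently, so homozygotes arise at Hardy-Weinberg rates.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    rng = _as_rng(seed)
    alleles = list(frequencies["allele"])
    if len(set(alleles)) != len(alleles):
        raise ValueError("allele names must be unique across loci")
    index = {a: j for j, a in enumerate(alleles)}
    copy_matrix = np.zeros((n_subjects, len(alleles)), dtype=int)
    for _, grp in frequencies.groupby("locus", sort=False):
        p = grp["frequency"].to_numpy(dtype=float)
        p = p / p.sum()
        cols = [index[a] for a in grp["allele"]]
        for _ in range(2):  # two chromosomes
            draws = rng.choice(cols, size=n_subjects, p=p)
            np.add.at(copy_matrix, (np.arange(n_subjects), draws), 1)
    return CohortTable(
        subject_ids=[f"G{i + 1:03d}" for i in range(n_subjects)],
        allele_names=alleles,
        copy_matrix=copy_matrix,
        responses=pd.DataFrame(index=pd.RangeIndex(n_subjects)),
    )


def resample_cohort(
    genotype_pool: CohortTable,
    n: int,
    seed: int | np.random.Generator = 0,
) -> CohortTable:
    """Draw *n* genotype rows uniformly with replacement from the pool."""
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    if genotype_pool.n_subjects == 0:
        raise ValueError("genotype pool is empty")
    rng = _as_rng(seed)
    picks = rng.integers(0, genotype_pool.n_subjects, size=n)
    return CohortTable(
        subject_ids=[f"R{i + 1:04d}" for i in range(n)],
        allele_names=list(genotype_pool.allele_names),
        copy_matrix=genotype_pool.copy_matrix[picks].copy(),
        responses=pd.DataFrame(index=pd.RangeIndex(n)),
    )


def draw_immunogenicities(
    m: int,
    upper: float = IMMUNOGENICITY_UPPER,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """m independent Uniform(0, upper) immunogenicities."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if upper < 0:
        raise ValueError("upper must be non-negative")
    rng = _as_rng(seed)
    return rng.uniform(0.0, upper, size=m) if upper > 0 else np.zeros(m)


def simulate_elispot(
    cohort: CohortTable,
    e_true: np.ndarray,
    seed: int | np.random.Generator = 0,
    peptide: str = "pep_1",
) -> CohortTable:
    """Bernoulli ELISpot outcomes for one peptide with truth *e_true*.

    Positive iff the uniform draw falls strictly below the subject's
    positive-ELISpot probability, so immunogenicity 0 everywhere gives
    all-negative and a carried immunogenicity of 1 forces a positive.
    """
    e_true = np.asarray(e_true, dtype=float)
    if e_true.shape != (cohort.n_alleles,):
        raise ValueError("e_true length must equal the number of alleles")
    rng = _as_rng(seed)
    with np.errstate(divide="ignore"):  # E=1 gives log 0 -> p_pos = 1 exactly
        p_pos = -np.expm1(cohort.copy_matrix @ np.log1p(-np.clip(e_true, 0.0, 1.0)))
    outcome = rng.random(cohort.n_subjects) < p_pos
    responses = cohort.responses.copy()
    responses[peptide] = pd.array(outcome, dtype="boolean")
    return CohortTable(
        subject_ids=list(cohort.subject_ids),
        allele_names=list(cohort.allele_names),
        copy_matrix=cohort.copy_matrix.copy(),
        responses=responses,
    )


def simulate_study(
    genotype_pool: CohortTable,
    n: int,
    n_peptides: int = DEFAULT_N_PEPTIDES,
    upper: float = IMMUNOGENICITY_UPPER,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[CohortTable, pd.DataFrame]:
    """One full synthetic study: resampled cohort + outcomes for several peptides.

    Returns the cohort (peptide columns ``pep_1 .. pep_K``) and a long
    ground-truth table (peptide, allele, e_true).  Deterministic under seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(1 + 2 * n_peptides)
    cohort = resample_cohort(genotype_pool, n, _as_rng(child[0]))
    truth_rows = []
    for k in range(n_peptides):
        pep = f"pep_{k + 1}"
        e_true = draw_immunogenicities(cohort.n_alleles, upper, _as_rng(child[1 + 2 * k]))
        cohort = simulate_elispot(cohort, e_true, _as_rng(child[2 + 2 * k]), peptide=pep)
        truth_rows.append(
            pd.DataFrame({"peptide": pep, "allele": cohort.allele_names, "e_true": e_true})
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return cohort, truth


def odds_ratios(cohort: CohortTable) -> pd.Series:
    """Per-peptide odds of a positive ELISpot (positives / negatives).

    The calibration hook for matching simulated response odds to a real
    dataset's; peptides with no negatives map to +inf.
    """
    out = {}
    for pep in cohort.peptides:
        resp = cohort.response_vector(pep).dropna()
        pos = int(resp.sum())
        neg = len(resp) - pos
        out[pep] = np.inf if neg == 0 else pos / neg
    return pd.Series(out, name="odds_ratio")
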