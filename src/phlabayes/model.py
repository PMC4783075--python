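"""Cohort container and the ELISpot likelihood.

The central quantity is the per-allele immunogenicity vector
``E = (E_1, ..., E_m)`` on the unit hypercube: ``E_j`` is (approximately)
the probability that presentation of the analysed peptide by HLA molecule
``j`` produces a positive ELISpot in a carrier.  For a subject ``i`` with
allele copy numbers ``n_ij`` the probability of a *negative* ELISpot is

    P(neg_i | E) = prod_j (1 - E_j) ** n_ij

i.e. every chromosomal copy of every carried allele independently fails to
elicit a response; a positive outcome has the complementary probability.
The cohort likelihood is the product over subjects with a recorded outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import re

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CohortTable", "RunConfig", "subject_likelihood", "cohort_log_likelihood"]

_FOUR_DIGIT = re.compile(r"^(?P<parent>.+_\d{2})_\d{2}$")


@dataclass(frozen=True)
class RunConfig:
    """Sampler and summary settings.

    Parameters
    ----------
    chain_length
        Number of Metropolis-Hastings iterations (default 100,000, the
        length at which marginals match those of ten-fold longer chains).
    burn_in_fraction
        Leading fraction of the chain discarded before summarising.
    proposal_step
        Per-coordinate SD of the reflected Gaussian random-walk proposal.
    seed
        Seed for all randomness of a run.
    density_bins
        Number of equal-width histogram bins on [0, 1] shared by the
        marginal mode estimator and the KL informativeness estimator.
    likelihood_clip_epsilon
        Lower clip for per-subject probabilities (and for Beta densities
        evaluated at the boundary) so log targets are always finite.
    """

    chain_length: int = 100_000
    burn_in_fraction: float = 0.1
    proposal_step: float = 0.05
    seed: int = 0
    density_bins: int = 100
    likelihood_clip_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.proposal_step <= 0:
            raise ValueError("proposal_step must be positive")
        if self.density_bins < 1:
            raise ValueError("density_bins must be positive")
        if self.likelihood_clip_epsilon <= 0:
            raise ValueError("likelihood_clip_epsilon must be positive")

    @property
    def n_kept(self) -> int:
        """Number of post-burn-in samples a chain of this config retains."""
        return int(self.chain_length * (1.0 - self.burn_in_fraction))


@dataclass
class CohortTable:
    """One genotyped, ELISpot-phenotyped cohort.

    ``copy_matrix`` holds integer allele copy numbers ``n_ij`` (0, 1 or 2);
    ``responses`` holds one nullable-boolean column per peptide (``pd.NA``
    marks a missing ELISpot for that subject/peptide).
    """

    subject_ids: list[str]
    allele_names: list[str]
    copy_matrix: np.ndarray
    responses: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.copy_matrix = np.asarray(self.copy_matrix)
        if self.copy_matrix.ndim != 2:
            raise ValueError("copy_matrix must be 2-dimensional")
        n, m = self.copy_matrix.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match copy_matrix rows")
        if len(self.allele_names) != m:
            raise ValueError("allele_names length does not match copy_matrix columns")
        if len(set(self.allele_names)) != m:
            raise ValueError("allele_names must be unique")
        if not np.issubdtype(self.copy_matrix.dtype, np.integer):
            as_int = self.copy_matrix.astype(int)
            if not np.array_equal(as_int, self.copy_matrix):
                raise ValueError("copy numbers must be integers")
            self.copy_matrix = as_int
        if self.copy_matrix.min(initial=0) < 0 or self.copy_matrix.max(initial=0) > 2:
            raise ValueError("copy numbers must lie in {0, 1, 2}")
        if n and (self.copy_matrix.sum(axis=1) == 0).any():
            bad = int(np.flatnonzero(self.copy_matrix.sum(axis=1) == 0)[0])
            raise ValueError(
                f"subject {self.subject_ids[bad]!r} carries no allele (all copy numbers zero)"
            )
        _check_single_resolution(self.allele_names)
        if len(self.responses) not in (0, n):
            raise ValueError("responses must have one row per subject")
        if len(self.responses):
            self.responses = self.responses.astype("boolean")
            self.responses.index = pd.RangeIndex(n)

    # -- convenience -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.copy_matrix.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.copy_matrix.shape[1]

    @property
    def peptides(self) -> list[str]:
        return list(self.responses.columns)

    def allele_index(self, allele: str) -> int:
        try:
            return self.allele_names.index(allele)
        except ValueError:
            raise KeyError(f"allele {allele!r} not in cohort") from None

    def response_vector(self, peptide: str) -> pd.Series:
        if peptide not in self.responses.columns:
            raise KeyError(
                f"peptide {peptide!r} not in cohort; available: {self.peptides}"
            )
        return self.responses[peptide]

    def observed(self, peptide: str) -> tuple[np.ndarray, np.ndarray]:
        """Copy matrix and boolean outcomes for subjects with a recorded
        ELISpot for *peptide*; missing-response subjects are dropped."""
        resp = self.response_vector(peptide)
        keep = resp.notna().to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "peptide %s: dropped %d subject(s) with missing ELISpot", peptide, n_dropped
            )
        return self.copy_matrix[keep], resp[keep].to_numpy(dtype=bool)

    def carrier_counts(self, peptide: str) -> pd.DataFrame:
        """Per-allele carrier and positive-carrier counts (carrier := n_ij >= 1)."""
        copies, outcome = self.observed(peptide)
        carrier = copies >= 1
        return pd.DataFrame(
            {
                "allele": self.allele_names,
                "n_carriers": carrier.sum(axis=0).astype(int),
                "n_carriers_positive": (carrier & outcome[:, None]).sum(axis=0).astype(int),
            }
        )


def _check_single_resolution(names: list[str]) -> None:
    present = set(names)
    for name in names:
        match = _FOUR_DIGIT.match(name)
        if match and match.group("parent") in present:
            raise ValueError(
                f"allele {name!r} and its two-digit parent {match.group('parent')!r} "
                "both present: each allele must appear at exactly one typing resolution"
            )


def _validate_hypothesis(E: np.ndarray, m: int) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.shape != (m,):
        raise ValueError(f"hypothesis has length {E.shape}, expected ({m},)")
    if np.any((E < 0.0) | (E > 1.0)) or not np.all(np.isfinite(E)):
        raise ValueError("immunogenicities must lie in [0, 1]")
    return E


def subject_likelihood(copy_row: np.ndarray, outcome: bool | str, E: np.ndarray) -> float:
    """Probability of one subject's ELISpot outcome given immunogenicities E.

    *outcome* may be a bool or the strings ``"positive"``/``"negative"``.
    Alleles the subject does not carry (copy number 0) contribute a factor 1.
    """
    copy_row = np.asarray(copy_row)
    E = _validate_hypothesis(E, len(copy_row))
    if isinstance(outcome, str):
        if outcome not in ("positive", "negative"):
            raise ValueError("outcome must be 'positive' or 'negative'")
        positive = outcome == "positive"
    else:
        positive = bool(outcome)
    p_negative = float(np.prod((1.0 - E) ** copy_row))
    return 1.0 - p_negative if positive else p_negative


def _log_p_negative(copies: np.ndarray, E_batch: np.ndarray) -> np.ndarray:
    """log prod_j (1-E_j)^n_ij for each subject x each hypothesis.

    ``E_batch`` is (K, m); returns (N, K).  Components at exactly 1 give
    -inf here; callers clip downstream.
    """
    with np.errstate(divide="ignore"):
        log1m = np.log1p(-E_batch)  # (K, m), -inf allowed at E=1
    out = copies @ log1m.T
    return out


def cohort_log_likelihood_batch(
    copies: np.ndarray,
    outcome: np.ndarray,
    E_batch: np.ndarray,
    clip_epsilon: float = 1e-12,
) -> np.ndarray:
    """Vectorised cohort log-likelihood for K hypotheses at once.

    Per-subject probabilities are clipped to ``[clip_epsilon, 1]`` before
    logging, so the result is always finite.  Returns shape (K,).
    """
    E_batch = np.atleast_2d(np.asarray(E_batch, dtype=float))
    if copies.shape[0] == 0:
        return np.zeros(E_batch.shape[0])
    log_eps = np.log(clip_epsilon)
    logq = _log_p_negative(copies, E_batch)  # (N, K)
    # negative subjects: log q, clipped below
    neg_term = np.maximum(logq, log_eps)
    # positive subjects: log(1 - q) = log(-expm1(log q)), clipped below
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_term = np.log(np.maximum(-np.expm1(logq), clip_epsilon))
    pos_term = np.minimum(pos_term, 0.0)
    terms = np.where(outcome[:, None], pos_term, neg_term)
    return terms.sum(axis=0)


def cohort_log_likelihood(
    cohort: CohortTable,
    peptide: str,
    E: np.ndarray,
    clip_epsilon: float = 1e-12,
) -> float:
    """Log-likelihood of one peptide's cohort data under hypothesis E.

    Subjects with a missing ELISpot value for *peptide* are excluded from
    the product.  Always finite by the clipping contract.
    """
    E = _validate_hypothesis(E, cohort.n_alleles)
    copies, outcome = cohort.observed(peptide)
    if copies.shape[0] == 0:
        raise ValueError(f"peptide {peptide!r} has no recorded ELISpot outcomes")
    return float(cohort_log_likelihood_batch(copies, outcome, E[None, :], clip_epsilon)[0])
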