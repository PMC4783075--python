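"""Per-allele prior densities on [0, 1].

With no external information every allele gets the uniform prior.  When
peptide:HLA binding predictions (IC50, nM) are supplied, predicted binders
(IC50 strictly below 500 nM) receive an optimistic Beta prior with mode
0.35 and SD 0.2, and everything else — including combinations exactly at
the threshold and alleles absent from the prediction set — the skeptical
near-zero Beta prior with mode 0.001 and SD 0.15.  Beta shapes are found
numerically from (mode, SD) because those are the natural units in which
such beliefs are stated.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "BINDER_THRESHOLD_NM",
    "beta_from_mode_sd",
    "binder_prior",
    "non_binder_prior",
    "build_prior",
    "log_prior_density",
    "read_binding_predictions",
]

#: IC50 below which a predicted peptide:HLA pair counts as a binder.
BINDER_THRESHOLD_NM = 500.0

_BINDER_MODE_SD = (0.35, 0.2)
_NON_BINDER_MODE_SD = (0.001, 0.15)

# Supremum of the attainable SD at any interior mode: the nu -> 2 limit is
# Beta(1,1), i.e. the uniform, whose SD is sqrt(1/12).
_SD_SUP = math.sqrt(1.0 / 12.0)


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-allele priors, stored as Beta shapes.

    The uniform prior is Beta(1, 1); ``kinds`` records which alleles were
    assigned uniform vs informative Beta priors for reporting.
    """

    allele_names: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        m = len(self.allele_names)
        if not (len(self.alpha) == len(self.beta) == len(self.kinds) == m):
            raise ValueError("prior arrays must align with allele names")
        if np.any(np.asarray(self.alpha) <= 0) or np.any(np.asarray(self.beta) <= 0):
            raise ValueError("Beta shape parameters must be strictly positive")

    @classmethod
    def uniform(cls, allele_names: list[str]) -> "PriorSpec":
        m = len(allele_names)
        return cls(tuple(allele_names), np.ones(m), np.ones(m), ("uniform",) * m)

    @property
    def is_uniform(self) -> bool:
        return all(k == "uniform" for k in self.kinds)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw hypotheses from the prior; shape (m,) or (size, m)."""
        if size is None:
            return rng.beta(self.alpha, self.beta)
        return rng.beta(self.alpha, self.beta, size=(size, len(self.alpha)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele": list(self.allele_names),
                "kind": list(self.kinds),
                "alpha": self.alpha,
                "beta": self.beta,
            }
        )


def beta_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters with the given interior mode and SD.

    Parametrise by nu = alpha + beta > 2 so that the mode constraint
    mode = (alpha-1)/(nu-2) gives alpha = mode*(nu-2)+1; the SD is then a
    strictly decreasing function of nu and a one-dimensional root find
    recovers it.  Raises for (mode, sd) pairs no Beta with an interior
    mode can attain, naming the feasible SD range.
    """
    if not 0.0 < mode < 1.0:
        raise ValueError("mode must lie strictly inside (0, 1)")
    if sd <= 0.0:
        raise ValueError("sd must be positive")
    if sd >= _SD_SUP:
        raise ValueError(
            f"no Beta distribution with mode {mode} has SD {sd}; "
            f"the feasible range at this mode is (0, {_SD_SUP:.6f})"
        )

    def sd_at(nu: float) -> float:
        a = mode * (nu - 2.0) + 1.0
        b = (1.0 - mode) * (nu - 2.0) + 1.0
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))

    lo, hi = 2.0 + 1e-9, 1e9
    if not sd_at(hi) < sd < sd_at(lo):
        raise ValueError(
            f"no Beta distribution with mode {mode} has SD {sd}; "
            f"the feasible range at this mode is ({sd_at(hi):.3e}, {_SD_SUP:.6f})"
        )
    nu = brentq(lambda v: sd_at(v) - sd, lo, hi, xtol=1e-12, rtol=1e-14)
    alpha = mode * (nu - 2.0) + 1.0
    b = (1.0 - mode) * (nu - 2.0) + 1.0
    return float(alpha), float(b)


def binder_prior() -> tuple[float, float]:
    """Beta shapes of the predicted-binder prior (mode 0.35, SD 0.2)."""
    return beta_from_mode_sd(*_BINDER_MODE_SD)


def non_binder_prior() -> tuple[float, float]:
    """Beta shapes of the predicted-non-binder prior (mode 0.001, SD 0.15)."""
    return beta_from_mode_sd(*_NON_BINDER_MODE_SD)


def build_prior(
    cohort_alleles: list[str],
    predictions: dict[str, float] | pd.Series | None = None,
) -> PriorSpec:
    """One prior entry per cohort allele.

    Without predictions every allele is uniform.  With predictions, alleles
    whose predicted IC50 is strictly below 500 nM get the binder prior;
    all others, including alleles missing from the prediction set, get the
    non-binder prior (missing alleles are logged).
    """
    if predictions is None:
        return PriorSpec.uniform(cohort_alleles)
    if isinstance(predictions, pd.Series):
        predictions = predictions.to_dict()
    for allele, ic50 in predictions.items():
        if not ic50 > 0:
            raise ValueError(f"predicted IC50 for {allele!r} must be positive, got {ic50}")
    ab_bind = binder_prior()
    ab_non = non_binder_prior()
    alphas, betas, kinds = [], [], []
    for allele in cohort_alleles:
        if allele not in predictions:
            logger.warning(
                "allele %s missing from binding predictions; treated as non-binder", allele
            )
            a, b, kind = *ab_non, "non_binder"
        elif predictions[allele] < BINDER_THRESHOLD_NM:
            a, b, kind = *ab_bind, "binder"
        else:
            a, b, kind = *ab_non, "non_binder"
        alphas.append(a)
        betas.append(b)
        kinds.append(kind)
    return PriorSpec(tuple(cohort_alleles), np.array(alphas), np.array(betas), tuple(kinds))


def log_prior_density_batch(
    prior: PriorSpec, E_batch: np.ndarray, clip_epsilon: float = 1e-12
) -> np.ndarray:
    """Sum of per-allele log densities for each hypothesis row in (K, m)."""
    E_batch = np.atleast_2d(np.asarray(E_batch, dtype=float))
    if np.all(prior.alpha == 1.0) and np.all(prior.beta == 1.0):
        return np.zeros(E_batch.shape[0])
    # clip so Beta densities with a shape parameter < 1 stay finite at 0/1
    x = np.clip(E_batch, clip_epsilon, 1.0 - clip_epsilon)
    logpdf = beta_dist.logpdf(x, prior.alpha, prior.beta)
    return logpdf.sum(axis=1)


def log_prior_density(prior: PriorSpec, E: np.ndarray, clip_epsilon: float = 1e-12) -> float:
    """Log joint prior density at one hypothesis (uniform components add 0)."""
    E = np.asarray(E, dtype=float)
    if E.shape != (len(prior.allele_names),):
        raise ValueError("hypothesis length does not match prior")
    return float(log_prior_density_batch(prior, E[None, :], clip_epsilon)[0])


def read_binding_predictions(path) -> dict[str, float]:
    """Read a two-column CSV (allele, ic50_nM) of binding predictions."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("binding prediction file needs columns (allele, ic50_nM)")
    allele_col, ic50_col = frame.columns[:2]
    return dict(zip(frame[allele_col].astype(str), frame[ic50_col].astype(float)))
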