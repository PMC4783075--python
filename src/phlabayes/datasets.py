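"""Bundled synthetic datasets.

Everything here is generated in code — no measured cohort data ships with
the package.

``worked_example_cohort`` builds a deterministic synthetic cohort whose
pep_1 carrier/response structure produces the canonical walk-through of
the attribution logic: a dominant allele (DQB_03) explains all of its
positive carriers, a second allele (DRB1_14) explains only the positives
that do not also carry the dominant allele, and a common allele (DQB_02)
with many positive carriers explains none of them because each of those
carriers also carries a higher-ranked allele.

``default_allele_frequencies`` is a synthetic DRB1/DQB1 class II
allele-frequency table, in the spirit of a small melioidosis-endemic
cohort, used to generate genotype pools for the simulation study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CohortTable

__all__ = ["worked_example_cohort", "default_allele_frequencies"]


def worked_example_cohort() -> CohortTable:
    """Synthetic 110-subject cohort with alleles DQB_03, DRB1_14, DQB_02.

    pep_1 ground facts, by construction:

    * DQB_03: 73 carriers, 67 with a positive ELISpot;
    * DRB1_14: 28 carriers, 25 positive, 11 of whom also carry DQB_03;
    * DQB_02: 76 carriers, 54 positive, every positive carrier also
      carries DQB_03 or DRB1_14, and 20 sole carriers are all negative.

    The joint model therefore infers a high immunogenicity for DQB_03,
    an intermediate one for DRB1_14 and a near-zero one for DQB_02,
    although DQB_02's naive positive-carrier fraction (54/76) looks high.

    pep_2 is a second, simpler peptide (positive exactly for DRB1_14
    carriers) so multi-peptide code paths have something to chew on.
    """
    # (n_DQB_03, n_DRB1_14, n_DQB_02, pep_1 outcome, group size)
    groups = [
        ((2, 0, 0), True, 2),   # homozygous DQB_03, positive
        ((1, 0, 0), True, 9),   # DQB_03 only, positive
        ((1, 0, 1), True, 45),  # DQB_03 + DQB_02, positive
        ((1, 1, 0), True, 11),  # DQB_03 + DRB1_14, positive
        ((0, 1, 0), True, 5),   # DRB1_14 only, positive
        ((0, 1, 1), True, 9),   # DRB1_14 + DQB_02, positive
        ((1, 0, 0), False, 4),  # DQB_03 only, negative
        ((1, 0, 1), False, 2),  # DQB_03 + DQB_02, negative
        ((0, 1, 0), False, 3),  # DRB1_14 only, negative
        ((0, 0, 2), False, 4),  # homozygous DQB_02, negative
        ((0, 0, 1), False, 16), # DQB_02 only, negative
    ]
    rows, pep_1 = [], []
    for copies, positive, size in groups:
        rows.extend([copies] * size)
        pep_1.extend([positive] * size)
    copy_matrix = np.array(rows, dtype=int)
    pep_2 = (copy_matrix[:, 1] >= 1).tolist()
    n = len(rows)
    return CohortTable(
        subject_ids=[f"S{i + 1:03d}" for i in range(n)],
        allele_names=["DQB_03", "DRB1_14", "DQB_02"],
        copy_matrix=copy_matrix,
        responses=pd.DataFrame({"pep_1": pep_1, "pep_2": pep_2}, dtype="boolean"),
    )


def default_allele_frequencies() -> pd.DataFrame:
    """Synthetic class II allele frequencies (columns: locus, allele, frequency).

    Two-digit resolution except DRB1*15, split into its two common
    subtypes as real typing often is.  Frequencies sum to 1 per locus.
    """
    drb1 = {
        "DRB1_01": 0.04,
        "DRB1_03": 0.06,
        "DRB1_04": 0.08,
        "DRB1_07": 0.10,
        "DRB1_08": 0.05,
        "DRB1_09": 0.07,
        "DRB1_11": 0.09,
        "DRB1_12": 0.10,
        "DRB1_14": 0.09,
        "DRB1_15_01": 0.14,
        "DRB1_15_02": 0.08,
        "DRB1_16": 0.10,
    }
    dqb1 = {
        "DQB_02": 0.14,
        "DQB_03": 0.33,
        "DQB_04": 0.09,
        "DQB_05": 0.20,
        "DQB_06": 0.24,
    }
    records = [("DRB1", a, f) for a, f in drb1.items()]
    records += [("DQB1", a, f) for a, f in dqb1.items()]
    return pd.DataFrame(records, columns=["locus", "allele", "frequency"])
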