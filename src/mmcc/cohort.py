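"""Cohort-level bookkeeping arithmetic.

Small, exactly-checkable computations over cohort summary counts: QC
singleton-count consistency across data layers vs. case/control splits,
open-chromatin overlap percentages against reference DHS annotations,
and autoantibody/endotype percentages of a case series.  The reference
counts below describe the longitudinal type 1 diabetes cohort design
(49 matched case-control pairs, three time points, three data layers)
that the synthetic generator emulates.
"""

from __future__ import annotations

import numpy as np

#: Reference cohort design summary used for consistency checks and as the
#: template the simulator's endotype fractions are derived from.
REFERENCE_COHORT = {
    "n_cases": 49,
    "n_controls": 49,
    "qc_singletons_per_layer": {"scRNA": 187_995, "snRNA": 186_449, "snATAC": 263_308},
    "qc_singletons_by_status": {"case": 307_746, "control": 330_006},
    "n_snatac_peaks": 99_779,
    "dhs_overlap": {"lymphoid": 34_555, "myeloid": 22_707, "total": 51_208},
    "antibody_counts": {"IAA": 44, "GADA": 43, "IA2A": 40, "ZnT8A": 31},
    "endotype_counts": {
        "IAA_first_strict": 21,
        "IAA_first_loose_cumulative": 38,
        "GADA_first_strict": 8,
        "GADA_first_loose_cumulative": 11,
    },
}


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def dhs_overlap_percent(cohort: dict | None = None, ndigits: int = 1) -> float:
    """Fraction of called peaks overlapping reference DHS regions, in %."""
    cohort = REFERENCE_COHORT if cohort is None else cohort
    return percent(cohort["dhs_overlap"]["total"], cohort["n_snatac_peaks"], ndigits)


def qc_counts_consistent(cohort: dict | None = None) -> bool:
    """Do per-layer QC singleton counts equal the case+control totals?"""
    cohort = REFERENCE_COHORT if cohort is None else cohort
    by_layer = sum(cohort["qc_singletons_per_layer"].values())
    by_status = sum(cohort["qc_singletons_by_status"].values())
    return by_layer == by_status


def antibody_percentages(cohort: dict | None = None, ndigits: int = 1) -> dict[str, float]:
    """Per-antibody positivity percentages among cases."""
    cohort = REFERENCE_COHORT if cohort is None else cohort
    n = cohort["n_cases"]
    return {ab: percent(k, n, ndigits) for ab, k in cohort["antibody_counts"].items()}


def endotype_percentages(cohort: dict | None = None, ndigits: int = 1) -> dict[str, float]:
    """Endotype percentages among cases (cumulative loose convention)."""
    cohort = REFERENCE_COHORT if cohort is None else cohort
    n = cohort["n_cases"]
    return {k: percent(v, n, ndigits) for k, v in cohort["endotype_counts"].items()}


def mean_singletons_per_sample(cohort: dict | None = None) -> float:
    """Average QC'd singletons per (donor, timepoint), pooled over layers."""
    cohort = REFERENCE_COHORT if cohort is None else cohort
    total = sum(cohort["qc_singletons_per_layer"].values())
    n_samples = (cohort["n_cases"] + cohort["n_controls"]) * 3
    return float(np.round(total / n_samples, 1))
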