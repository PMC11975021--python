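"""Autoantibody-order endotype classification, subgroup differential
analysis, and overlap with the overall case-control signal.

Endotypes are defined by the autoantibody content of the first
autoantibody-positive sample: IAA alone is IAA-first (strict); multiple
antibodies including IAA but not GADA is IAA-first (loose); GADA
symmetrically; samples containing both IAA and GADA (or neither) fall in
"other".  The internal labels are mutually exclusive; group selection
offers the cumulative convention in which a loose group includes its
strict members (the convention cohort tables typically use).
"""

from __future__ import annotations

import pandas as pd

from mmcc.differential import run_differential
from mmcc.replication import assess_replication, replicated_sets
from mmcc.types import Pseudobulk

ANTIBODIES = ("IAA", "GADA", "IA2A", "ZnT8A")


def classify_endotype(first_positive_sample_antibodies: set[str]) -> str:
    """Endotype label from the antibody set of the first positive sample."""
    abs_ = set(first_positive_sample_antibodies)
    if not abs_:
        raise ValueError("a case must have at least one antibody in its first positive sample")
    unknown = abs_ - set(ANTIBODIES)
    if unknown:
        raise ValueError(f"unknown antibodies {sorted(unknown)}")
    has_iaa, has_gada = "IAA" in abs_, "GADA" in abs_
    if abs_ == {"IAA"}:
        return "IAA_first_strict"
    if abs_ == {"GADA"}:
        return "GADA_first_strict"
    if has_iaa and not has_gada:
        return "IAA_first_loose"
    if has_gada and not has_iaa:
        return "GADA_first_loose"
    return "other"


def select_endotype_cases(
    samples: pd.DataFrame, group: str, cumulative: bool = True
) -> list[str]:
    """Case donor ids in an endotype group.

    ``group`` may be a specific label (``"IAA_first_strict"``) or a
    family (``"IAA_first"`` / ``"GADA_first"``).  With ``cumulative``
    (default) a loose label includes the strict members, matching the
    usual cohort-table counting.
    """
    cases = samples[samples["status"] == "case"]
    labels = cases["endotype"]
    if group.endswith("_strict") or group == "other":
        mask = labels == group
    elif group.endswith("_loose"):
        family = group[: -len("_loose")]
        mask = (
            labels.isin([f"{family}_strict", f"{family}_loose"])
            if cumulative
            else (labels == group)
        )
    else:  # family name
        mask = labels.isin([f"{group}_strict", f"{group}_loose"])
    return list(cases.loc[mask, "donor_id"])


def endotype_differential(
    pseudobulks: dict[str, Pseudobulk],
    samples: pd.DataFrame,
    group: str,
    fdr: float = 0.10,
    cumulative: bool = True,
    links: pd.DataFrame | None = None,
    min_layers: int = 2,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Subgroup differential + replication against matched controls.

    Runs the standard differential machinery restricted to the subgroup's
    cases and their matched pair controls, for every supplied modality,
    then builds replication records across those subgroup-specific runs.

    Returns (differential tables by modality, replication records).
    """
    subset = select_endotype_cases(samples, group, cumulative=cumulative)
    if not subset:
        raise ValueError(f"endotype group {group!r} has no cases")
    results = {
        m: run_differential(pb, samples, fdr=fdr, case_subset=subset)
        for m, pb in pseudobulks.items()
    }
    records = assess_replication(results, links=links, q_threshold=fdr, min_layers=min_layers)
    return results, records


def overlap_with_overall(
    subgroup_records: pd.DataFrame, overall_records: pd.DataFrame
) -> pd.DataFrame:
    """Per (lineage, timepoint, direction) overlap fraction.

    fraction = |overall ∩ subgroup, same direction| / |overall| for the
    replicated-signal sets; strata with an empty overall set get a
    missing fraction.
    """
    sub_sets = replicated_sets(subgroup_records)
    overall_sets = replicated_sets(overall_records)
    rows = []
    for key, overall in sorted(overall_sets.items()):
        sub = sub_sets.get(key, set())
        lineage, timepoint, direction = key
        rows.append(
            {
                "lineage": lineage,
                "timepoint": timepoint,
                "direction": direction,
                "n_overall": len(overall),
                "n_subgroup": len(sub),
                "n_overlap": len(overall & sub),
                "fraction": len(overall & sub) / len(overall) if overall else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lineage", "timepoint", "direction", "n_overall", "n_subgroup", "n_overlap", "fraction"],
    )
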