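import itertools

import pandas as pd
import pytest

from mmcc.endotype import (
    ANTIBODIES,
    classify_endotype,
    overlap_with_overall,
    select_endotype_cases,
)


@pytest.mark.parametrize(
    "abs_,expected",
    [
        ({"IAA"}, "IAA_first_strict"),
        ({"GADA"}, "GADA_first_strict"),
        ({"IAA", "IA2A"}, "IAA_first_loose"),
        ({"GADA", "ZnT8A", "IA2A"}, "GADA_first_loose"),
        ({"IAA", "GADA"}, "other"),
        ({"IA2A"}, "other"),
        ({"IA2A", "ZnT8A"}, "other"),
    ],
)
def test_classification_examples(abs_, expected):
    assert classify_endotype(abs_) == expected


def test_classification_total_and_mutually_exclusive():
    """Every nonempty subset of the four antibodies maps to exactly one
    label, and strict labels only arise from singleton sets."""
    for r in range(1, 5):
        for combo in itertools.combinations(ANTIBODIES, r):
            label = classify_endotype(set(combo))
            if label.endswith("_strict"):
                assert len(combo) == 1
            if "IAA" in combo and "GADA" in combo:
                assert label == "other"


def test_empty_set_rejected():
    with pytest.raises(ValueError):
        classify_endotype(set())
    with pytest.raises(ValueError):
        classify_endotype({"XYZ"})


def _samples():
    return pd.DataFrame(
        {
            "donor_id": ["c1", "c2", "c3", "c4", "n1", "n2", "n3", "n4"],
            "status": ["case"] * 4 + ["control"] * 4,
            "pair_id": ["P1", "P2", "P3", "P4"] * 2,
            "endotype": ["GADA_first_strict", "GADA_first_loose", "IAA_first_strict", "other"]
            + ["none"] * 4,
            "seroconversion_age": [2.0] * 4 + [float("nan")] * 4,
        }
    )


def test_cumulative_selection_includes_strict_in_loose():
    samples = _samples()
    assert set(select_endotype_cases(samples, "GADA_first_loose")) == {"c1", "c2"}
    assert set(select_endotype_cases(samples, "GADA_first_loose", cumulative=False)) == {"c2"}
    assert set(select_endotype_cases(samples, "GADA_first")) == {"c1", "c2"}
    assert set(select_endotype_cases(samples, "IAA_first_strict")) == {"c3"}


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["feature_id", "lineage", "timepoint", "modality", "direction", "replicated"],
    )


def test_overlap_fraction_extremes():
    overall = _records(
        [("g1", "Monocyte", "T1", "snRNA", "up_in_cases", True),
         ("g2", "Monocyte", "T1", "snRNA", "up_in_cases", True)]
    )
    superset = _records(
        [("g1", "Monocyte", "T1", "snRNA", "up_in_cases", True),
         ("g2", "Monocyte", "T1", "snRNA", "up_in_cases", True),
         ("g3", "Monocyte", "T1", "snRNA", "up_in_cases", True)]
    )
    disjoint = _records([("g9", "Monocyte", "T1", "snRNA", "up_in_cases", True)])
    assert overlap_with_overall(superset, overall).iloc[0]["fraction"] == 1.0
    assert overlap_with_overall(disjoint, overall).iloc[0]["fraction"] == 0.0


def test_direction_must_match_in_overlap():
    overall = _records([("g1", "B", "T2", "snRNA", "up_in_cases", True)])
    flipped = _records([("g1", "B", "T2", "snRNA", "up_in_controls", True)])
    out = overlap_with_overall(flipped, overall)
    assert out.iloc[0]["fraction"] == 0.0


def test_subgroup_of_all_cases_matches_full_run(tiny_bundle):
    from mmcc.differential import run_differential
    from mmcc.endotype import endotype_differential
    from mmcc.pseudobulk import make_pseudobulk

    bundle, _ = tiny_bundle
    pbs = {"snRNA": make_pseudobulk(bundle.layers["snRNA"], bundle.cells)}
    # every simulated case carries some endotype label, so selecting all
    # families jointly reproduces the full analysis
    full = run_differential(pbs["snRNA"], bundle.samples)
    all_cases = list(bundle.samples.loc[bundle.samples["status"] == "case", "donor_id"])
    sub = run_differential(pbs["snRNA"], bundle.samples, case_subset=all_cases)
    pd.testing.assert_frame_equal(full, sub)


def test_unknown_group_errors(tiny_bundle):
    from mmcc.endotype import endotype_differential
    from mmcc.pseudobulk import make_pseudobulk

    bundle, _ = tiny_bundle
    pbs = {"snRNA": make_pseudobulk(bundle.layers["snRNA"], bundle.cells)}
    with pytest.raises(ValueError, match="no cases"):
        endotype_differential(pbs, bundle.samples.assign(endotype="none"), "GADA_first")
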