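"""Generator contracts: determinism, planted structure, count model."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_config
from mmcc.pseudobulk import make_pseudobulk
from mmcc.simulate import (
    PlantedEffect,
    PlantedQtl,
    SimConfig,
    default_recovery_config,
    simulate_cohort,
    simulate_null,
)


def test_same_seed_gives_identical_bundles():
    b1, t1 = simulate_cohort(tiny_config(seed=3))
    b2, t2 = simulate_cohort(tiny_config(seed=3))
    for m in b1.layers:
        assert (b1.layers[m].matrix != b2.layers[m].matrix).nnz == 0
    pd.testing.assert_frame_equal(b1.cells, b2.cells)
    pd.testing.assert_frame_equal(b1.samples, b2.samples)
    pd.testing.assert_frame_equal(b1.genotypes, b2.genotypes)
    assert t1.to_json() == t2.to_json()


def test_different_seed_changes_counts():
    b1, _ = simulate_cohort(tiny_config(seed=3))
    b2, _ = simulate_cohort(tiny_config(seed=4))
    assert (b1.layers["snRNA"].matrix != b2.layers["snRNA"].matrix).nnz > 0


def test_null_simulation_has_empty_truth():
    _, truth = simulate_null(tiny_config(seed=5))
    assert truth.effects == [] and truth.links == [] and truth.qtls == []


def test_unknown_planted_feature_rejected_before_simulation():
    cfg = tiny_config(effects=[PlantedEffect("NOPE", "Monocyte", "T1", 1.0)])
    with pytest.raises(ValueError, match="NOPE"):
        simulate_cohort(cfg)


def test_bundle_passes_validation(tiny_bundle):
    bundle, _ = tiny_bundle
    bundle.validate()


def test_multiome_layers_share_nuclei_while_scrna_does_not(tiny_bundle):
    bundle, _ = tiny_bundle
    assert bundle.layers["snRNA"].cell_ids == bundle.layers["snATAC"].cell_ids
    assert set(bundle.layers["scRNA"].cell_ids).isdisjoint(bundle.layers["snRNA"].cell_ids)


def test_mean_library_size_matches_configuration(tiny_bundle):
    bundle, _ = tiny_bundle
    mean_reads = bundle.layers["snRNA"].matrix.sum() / bundle.layers["snRNA"].n_cells
    # Poisson library sizes: relative SE of the mean ~ 1/sqrt(n_cells * depth)
    assert mean_reads == pytest.approx(800, rel=0.02)


def test_pooled_proportions_agree_between_rna_layers(tiny_bundle):
    """snRNA and scRNA draw from the same donor-level means, so pooled
    feature proportions agree up to sampling error."""
    bundle, _ = tiny_bundle
    p1 = np.asarray(bundle.layers["snRNA"].matrix.sum(axis=0)).ravel()
    p2 = np.asarray(bundle.layers["scRNA"].matrix.sum(axis=0)).ravel()
    p1 = p1 / p1.sum()
    p2 = p2 / p2.sum()
    assert np.corrcoef(p1, p2)[0, 1] > 0.999


def test_planted_twofold_effect_yields_twofold_proportion_ratio():
    """Monte-Carlo oracle: averaging over replicate cohorts, the planted
    case/control proportion ratio in the target stratum approaches the
    planted fold."""
    ratios = []
    for rep in range(10):
        cfg = tiny_config(
            seed=600 + rep,
            effects=[PlantedEffect("G0005", "Monocyte", "T1", 1.0)],
        )
        bundle, _ = simulate_cohort(cfg)
        pb = make_pseudobulk(bundle.layers["snRNA"], bundle.cells)
        totals = pb.totals.xs("T1", level="timepoint").xs("Monocyte", level="lineage")
        status = dict(zip(bundle.samples["donor_id"], bundle.samples["status"]))
        case = totals[[status[d] == "case" for d in totals.index]]
        ctrl = totals[[status[d] == "control" for d in totals.index]]
        p_case = case["G0005"].sum() / case.to_numpy().sum()
        p_ctrl = ctrl["G0005"].sum() / ctrl.to_numpy().sum()
        ratios.append(p_case / p_ctrl)
    ratios = np.array(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 2.0) < 3 * se + 0.05


def test_planted_qtl_shows_monotone_dosage_trend():
    cfg = tiny_config(seed=21, qtls=[PlantedQtl("rs0001", "G0010", allele_fold=2.0)])
    bundle, _ = simulate_cohort(cfg)
    pb = make_pseudobulk(bundle.layers["snRNA"], bundle.cells).per_million()
    sig = pb["G0010"].groupby(level="donor_id").mean()
    geno = bundle.genotypes.set_index("snv_id")
    dosage = geno.loc["rs0001", sig.index].astype(float)
    means = sig.groupby(dosage).mean()
    assert means.is_monotonic_increasing


def test_endotype_counts_follow_fractions():
    bundle, truth = simulate_cohort(SimConfig(seed=9, n_pairs=49))
    counts = pd.Series(truth.endotypes).value_counts()
    assert counts["IAA_first_strict"] == 21
    assert counts["GADA_first_strict"] == 8
    assert counts["GADA_first_loose"] == 3
    controls = bundle.samples[bundle.samples["status"] == "control"]
    assert (controls["endotype"] == "none").all()


def test_recovery_config_references_valid_features():
    cfg = default_recovery_config(seed=0)
    cfg.validate()
    assert len(cfg.effects) == 40 and len(cfg.links) == 10 and len(cfg.qtls) == 5
    # QTL targets must sit inside the 1 Mb scan window of their SNV
    from mmcc.simulate import _feature_tables, snv_position

    genes_df, peaks_df = _feature_tables(cfg)
    tss = dict(zip(genes_df["gene_id"], zip(genes_df["chrom"], genes_df["tss"])))
    mid = dict(
        zip(peaks_df["peak_id"], zip(peaks_df["chrom"], (peaks_df["start"] + peaks_df["end"]) / 2))
    )
    for q in cfg.qtls:
        _, chrom, pos = snv_position(cfg, q.snv_id)
        fchrom, fpos = tss.get(q.feature_id) or mid[q.feature_id]
        assert fchrom == chrom and abs(fpos - pos) <= 1e6


def test_overdispersion_inflates_pooled_variance():
    """Per-cell gamma noise leaves means unchanged but makes pooled
    pseudobulk proportions overdispersed relative to multinomial."""
    disp = []
    for od in (0.0, 0.5):
        cfg = tiny_config(seed=77, overdispersion=od)
        bundle, _ = simulate_cohort(cfg)
        pb = make_pseudobulk(bundle.layers["snRNA"], bundle.cells)
        norm = pb.per_million()
        disp.append(norm.var(axis=0).mean())
    assert disp[1] > 1.5 * disp[0]
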