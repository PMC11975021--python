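import numpy as np
import pandas as pd
import pytest

from mmcc.qtl import encode_dosage, overlap_with_differential, qtl_scan


@pytest.mark.parametrize(
    "gt,expected", [("0/0", 0), ("0/1", 1), ("1/0", 1), ("1/1", 2), ("./.", None)]
)
def test_encode_dosage(gt, expected):
    assert encode_dosage(gt) == expected


def test_encode_dosage_rejects_garbage():
    with pytest.raises(ValueError):
        encode_dosage("2/1")


def _norm_frame(signal, donors, feature="G1"):
    idx = pd.MultiIndex.from_tuples(
        [(d, "T1", "Monocyte") for d in donors],
        names=["donor_id", "timepoint", "lineage"],
    )
    return pd.DataFrame({feature: signal}, index=idx)


def _geno(donors, dosages, snv="rs1", chrom="chr1", pos=500):
    row = {"snv_id": snv, "chrom": chrom, "pos": pos}
    row.update(dict(zip(donors, dosages)))
    return pd.DataFrame([row])


GENES = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"], "tss": [1000], "strand": ["+"]})
PEAKS = pd.DataFrame({"peak_id": ["P1"], "chrom": ["chr1"], "start": [2000], "end": [2500]})


def test_perfect_monotone_signal_gives_rho_one():
    # untied dosages: a strictly increasing signal attains rho = 1
    donors = ["D0", "D1", "D2"]
    out = qtl_scan(
        _geno(donors, [0, 1, 2]), {"snRNA": _norm_frame([1.0, 5.0, 9.0], donors)}, GENES, PEAKS
    )
    assert out.iloc[0]["rho"] == pytest.approx(1.0)
    # with tied dosages, midranks bound rho strictly below 1 even for a
    # strictly increasing signal
    donors9 = [f"D{i}" for i in range(9)]
    out9 = qtl_scan(
        _geno(donors9, [0, 0, 0, 1, 1, 1, 2, 2, 2]),
        {"snRNA": _norm_frame([1, 2, 3, 10, 11, 12, 20, 21, 22], donors9)},
        GENES, PEAKS,
    )
    assert 0.9 < out9.iloc[0]["rho"] < 1.0


def test_rho_invariant_to_monotone_transform():
    donors = [f"D{i}" for i in range(12)]
    rng = np.random.default_rng(3)
    dosages = rng.integers(0, 3, size=12)
    signal = rng.normal(size=12)
    base = qtl_scan(_geno(donors, list(dosages)), {"snRNA": _norm_frame(signal, donors)}, GENES, PEAKS)
    transformed = qtl_scan(
        _geno(donors, list(dosages)),
        {"snRNA": _norm_frame(np.exp(signal * 3), donors)},
        GENES, PEAKS,
    )
    assert base.iloc[0]["rho"] == pytest.approx(transformed.iloc[0]["rho"])
    assert base.iloc[0]["p"] == pytest.approx(transformed.iloc[0]["p"])


def test_monomorphic_snv_skipped():
    donors = [f"D{i}" for i in range(8)]
    out = qtl_scan(
        _geno(donors, [1] * 8), {"snRNA": _norm_frame(range(8), donors)}, GENES, PEAKS
    )
    assert len(out) == 0


def test_features_outside_window_not_tested():
    donors = [f"D{i}" for i in range(8)]
    far_genes = GENES.assign(tss=5_000_000)
    out = qtl_scan(
        _geno(donors, [0, 0, 1, 1, 1, 2, 2, 2]),
        {"snRNA": _norm_frame(range(8), donors)},
        far_genes, PEAKS,
    )
    assert len(out) == 0


def test_bonferroni_bounded_below_by_p_and_capped_at_one(tiny_bundle):
    from mmcc.pseudobulk import make_pseudobulk

    bundle, _ = tiny_bundle
    norm = {m: make_pseudobulk(l, bundle.cells).per_million() for m, l in bundle.layers.items()}
    out = qtl_scan(bundle.genotypes, norm, bundle.genes, bundle.peaks)
    assert len(out) > 0
    assert (out["p_bonf"] >= out["p"] - 1e-12).all()
    assert (out["p_bonf"] <= 1.0).all()
    assert out["rho"].between(-1, 1).all()


def test_permuted_dosages_give_uniform_pvalues():
    """Spearman p-values are approximately calibrated: ~5% of tests on
    permuted dosages fall below 0.05."""
    rng = np.random.default_rng(8)
    donors = [f"D{i}" for i in range(30)]
    rates = []
    for rep in range(20):
        dosages = rng.permutation([0] * 12 + [1] * 12 + [2] * 6)
        idx = pd.MultiIndex.from_tuples(
            [(d, "T1", "Monocyte") for d in donors],
            names=["donor_id", "timepoint", "lineage"],
        )
        sig = pd.DataFrame(
            rng.normal(size=(30, 50)), index=idx, columns=[f"G{i}" for i in range(50)]
        )
        genes = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(50)], "chrom": "chr1",
             "tss": np.arange(50) * 1000, "strand": "+"}
        )
        out = qtl_scan(_geno(donors, list(dosages)), {"snRNA": sig}, genes, PEAKS)
        rates.append((out["p"] < 0.05).mean())
    rate = np.mean(rates)
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(rate - 0.05) < 3 * se + 0.01


def test_overlap_report_flags_shared_features():
    qtl_hits = pd.DataFrame({"snv_id": ["rs1"], "feature_id": ["G1"]})
    diff = pd.DataFrame({"feature_id": ["G1"], "significant": [True]})
    geno = _geno(["D1"], [1])
    rep = overlap_with_differential(qtl_hits, diff, geno, GENES, PEAKS)
    assert rep.iloc[0]["overlaps"]
    assert rep.iloc[0]["n_differential_near"] == 1
    # no differential features near -> empty overlap
    rep2 = overlap_with_differential(
        qtl_hits.iloc[:0], diff.iloc[:0], geno, GENES, PEAKS
    )
    assert not rep2.iloc[0]["overlaps"]
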