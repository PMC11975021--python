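import numpy as np
import pandas as pd
import pytest

from mmcc.links import (
    candidate_pairs,
    classify_distance,
    link_correlation,
    link_density,
    validate_links,
)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def test_candidate_pair_distance_arithmetic():
    peaks = _peaks([("p1", "chr1", 100, 300)])
    genes = _genes([("g1", "chr1", 1200, "+"), ("g2", "chr2", 1200, "+")])
    pairs = candidate_pairs(peaks, genes)
    assert len(pairs) == 1
    assert pairs.iloc[0]["gene_id"] == "g1"
    assert pairs.iloc[0]["distance"] == 1000


def test_one_megabase_bound_is_closed():
    peaks = _peaks([("p1", "chr1", 0, 400)])  # midpoint 200
    genes = _genes([("gin", "chr1", 1_000_200, "+"), ("gout", "chr1", 1_000_201, "+")])
    pairs = candidate_pairs(peaks, genes)
    assert set(pairs["gene_id"]) == {"gin"}


def test_candidate_pairs_agree_with_brute_force(rng):
    peaks = _peaks(
        sorted(
            [
                (f"p{i}", rng.choice(["chr1", "chr2"]), s, s + 200)
                for i, s in enumerate(rng.integers(0, 3_000_000, size=40))
            ],
            key=lambda r: (r[1], r[2]),
        )
    )
    genes = _genes(
        [
            (f"g{i}", rng.choice(["chr1", "chr2"]), int(t), "+")
            for i, t in enumerate(rng.integers(0, 3_000_000, size=25))
        ]
    )
    pairs = candidate_pairs(peaks, genes)
    got = set(zip(pairs["peak_id"], pairs["gene_id"]))
    expected = set()
    for _, p in peaks.iterrows():
        for _, g in genes.iterrows():
            if p["chrom"] == g["chrom"] and abs((p["start"] + p["end"]) / 2 - g["tss"]) <= 1e6:
                expected.add((p["peak_id"], g["gene_id"]))
    assert got == expected


@pytest.mark.parametrize(
    "distance,expected",
    [
        (0, "promoter"),
        (3_000, "promoter"),
        (5_000, "proximal"),
        (19_999, "proximal"),
        (20_000, "distal"),
        (250_000, "distal"),
        (500_000, "long_range"),
        (1_000_000, "long_range"),
    ],
)
def test_distance_bins_partition_with_upward_boundaries(distance, expected):
    assert classify_distance(distance) == expected


def test_distance_out_of_range_errors():
    with pytest.raises(ValueError):
        classify_distance(-1)
    with pytest.raises(ValueError):
        classify_distance(1_000_001)


def _norm_frames(rng, n_obs=40, n_peaks=6, n_genes=6):
    idx = pd.MultiIndex.from_tuples(
        [(f"D{i}", "T1", "B") for i in range(n_obs)],
        names=["donor_id", "timepoint", "lineage"],
    )
    atac = pd.DataFrame(
        rng.normal(size=(n_obs, n_peaks)), index=idx, columns=[f"p{i}" for i in range(n_peaks)]
    )
    rna = pd.DataFrame(
        rng.normal(size=(n_obs, n_genes)), index=idx, columns=[f"g{i}" for i in range(n_genes)]
    )
    return atac, rna


def test_exact_affine_relation_gives_unit_correlation(rng):
    atac, rna = _norm_frames(rng)
    rna["g0"] = 3.0 * atac["p0"] + 7.0
    pairs = pd.DataFrame({"peak_id": ["p0"], "gene_id": ["g0"], "distance": [100], "bin": ["promoter"]})
    out = link_correlation(atac, rna, pairs)
    assert out.iloc[0]["r_discovery"] == pytest.approx(1.0)
    assert out.iloc[0]["nominal"]


def test_zero_variance_pair_skipped(rng):
    atac, rna = _norm_frames(rng)
    atac["p0"] = 5.0
    pairs = pd.DataFrame(
        {"peak_id": ["p0", "p1"], "gene_id": ["g0", "g1"], "distance": [1, 1], "bin": ["promoter"] * 2}
    )
    out = link_correlation(atac, rna, pairs)
    assert list(out["peak_id"]) == ["p1"]


def test_too_few_observations_rejected(rng):
    atac, rna = _norm_frames(rng, n_obs=4)
    pairs = pd.DataFrame({"peak_id": ["p0"], "gene_id": ["g0"], "distance": [1], "bin": ["promoter"]})
    with pytest.raises(ValueError, match="5"):
        link_correlation(atac, rna, pairs)


def test_validation_requires_sign_concordance_and_strict_threshold(rng):
    atac, rna = _norm_frames(rng, n_obs=200)
    links = pd.DataFrame(
        {
            "peak_id": ["p0", "p1"],
            "gene_id": ["g0", "g1"],
            "distance": [1, 1],
            "bin": ["promoter"] * 2,
            "r_discovery": [0.9, 0.9],
        }
    )
    # p0-g0 strongly negative in validation: sign discordant
    rna["g0"] = -atac["p0"] + 0.1 * rng.normal(size=len(atac))
    # p1-g1 positive but weak (|r| ~ 0.5 < 0.65)
    rna["g1"] = 0.6 * atac["p1"] + rng.normal(size=len(atac))
    out = validate_links(links, atac, rna)
    assert not out["validated"].any()
    assert out.loc[0, "r_validation"] < -0.9


def test_correlation_pvalues_calibrated_for_exchangeable_observations(rng):
    """With iid observations, ~5% of independent pairs pass p < 0.05."""
    rates = []
    for rep in range(5):
        atac, rna = _norm_frames(np.random.default_rng(100 + rep), n_obs=60, n_peaks=40, n_genes=40)
        pairs = pd.DataFrame(
            [(f"p{i}", f"g{j}", 1, "promoter") for i in range(40) for j in range(40)],
            columns=["peak_id", "gene_id", "distance", "bin"],
        )
        out = link_correlation(atac, rna, pairs)
        rates.append((out["p_discovery"] < 0.05).mean())
    rate = np.mean(rates)
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(rate - 0.05) < 3 * se + 0.005


def test_link_density_arithmetic():
    links = pd.DataFrame(
        {
            "peak_id": ["p1", "p2"],
            "gene_id": ["g1", "g1"],
            "distance": [1000, 2000],
            "bin": ["promoter", "promoter"],
        }
    )
    dens = link_density(links).set_index("bin")
    assert dens.loc["promoter", "links_per_kb"] == pytest.approx(2 / 5.0)
    assert dens.loc["distal", "links_per_kb"] == 0.0
    # doubling genes with identical structure leaves density unchanged
    links2 = pd.concat(
        [links, links.assign(gene_id="g2", peak_id=["p3", "p4"])], ignore_index=True
    )
    dens2 = link_density(links2).set_index("bin")
    assert dens2.loc["promoter", "links_per_kb"] == dens.loc["promoter", "links_per_kb"]
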