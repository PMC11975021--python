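"""Peak-gene cis linking within 1 Mb of the TSS.

Candidate pairs are all (peak, gene) on the same chromosome with peak
midpoint within 1 Mb of the gene's TSS (closed bound, strand-agnostic).
Discovery correlates the peak's normalized snATAC signal with the gene's
normalized snRNA signal across (donor, timepoint, lineage) pseudobulk
observations from the same multiome nuclei (Pearson, two-sided t
approximation); nominal links require p < 0.05 and |r| > 0.05.
Validation recomputes the correlation between the orthogonal unpaired
layers (snATAC vs scRNA); a link is validated when the validation r has
the same sign as discovery and |r| > 0.65.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DISTANCE_BINS = (
    ("promoter", 0, 5_000),
    ("proximal", 5_000, 20_000),
    ("distal", 20_000, 500_000),
    ("long_range", 500_000, 1_000_001),  # closed at 1 Mb
)


def classify_distance(distance: float) -> str:
    """Distance bin: promoter [0,5kb), proximal [5,20kb), distal
    [20,500kb), long_range [500kb,1Mb]."""
    if distance < 0 or distance > 1_000_000:
        raise ValueError(f"distance {distance} outside [0, 1 Mb]")
    for name, lo, hi in DISTANCE_BINS:
        if lo <= distance < hi:
            return name
    raise AssertionError("unreachable")


def candidate_pairs(
    peaks: pd.DataFrame, genes: pd.DataFrame, max_dist: float = 1e6
) -> pd.DataFrame:
    """All same-chromosome (peak, gene) pairs with |midpoint - TSS| <= max_dist.

    Returns columns peak_id, gene_id, distance, bin.
    """
    frames = []
    for chrom, psub in peaks.groupby("chrom", sort=True):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        mids = ((psub["start"] + psub["end"]) / 2.0).to_numpy()
        tss = gsub["tss"].to_numpy(dtype=float)
        order = np.argsort(tss, kind="stable")
        tss_sorted = tss[order]
        gids = gsub["gene_id"].to_numpy()[order]
        lo = np.searchsorted(tss_sorted, mids - max_dist, side="left")
        hi = np.searchsorted(tss_sorted, mids + max_dist, side="right")
        pid_arr = psub["peak_id"].to_numpy()
        for i in range(len(psub)):
            sel = slice(lo[i], hi[i])
            dist = np.abs(tss_sorted[sel] - mids[i])
            keep = dist <= max_dist
            frames.append(
                pd.DataFrame(
                    {
                        "peak_id": pid_arr[i],
                        "gene_id": gids[sel][keep],
                        "distance": dist[keep],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["peak_id", "gene_id", "distance", "bin"])
    pairs = pd.concat(frames, ignore_index=True)
    pairs["bin"] = [classify_distance(d) for d in pairs["distance"]]
    return pairs


def _pair_correlations(
    atac_norm: pd.DataFrame, rna_norm: pd.DataFrame, pairs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided t-approx p per pair.

    Observations are the common (donor, timepoint, lineage) keys of the
    two normalized pseudobulk tables.  Pairs where either vector has zero
    variance get r = p = NaN (skipped, logged by the caller).
    """
    common = atac_norm.index.intersection(rna_norm.index)
    n = len(common)
    if n < 5:
        raise ValueError(f"need >= 5 paired observations, got {n}")
    A = atac_norm.loc[common].to_numpy(dtype=float)
    R = rna_norm.loc[common].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (A - A.mean(axis=0)) / A.std(axis=0)
        R = (R - R.mean(axis=0)) / R.std(axis=0)
    pcol = atac_norm.columns.get_indexer(pairs["peak_id"])
    gcol = rna_norm.columns.get_indexer(pairs["gene_id"])
    with np.errstate(invalid="ignore"):
        r = np.einsum("ij,ij->j", A[:, pcol], R[:, gcol]) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p, np.full(len(pairs), n)


def link_correlation(
    atac_norm: pd.DataFrame,
    rna_norm: pd.DataFrame,
    pairs: pd.DataFrame,
    p_threshold: float = 0.05,
    r_threshold: float = 0.05,
) -> pd.DataFrame:
    """Discovery correlations for candidate pairs on the multiome layer.

    Returns all testable pairs with ``r_discovery``, ``p_discovery`` and a
    ``nominal`` flag (p < 0.05 and |r| > 0.05 by default).
    """
    r, p, n = _pair_correlations(atac_norm, rna_norm, pairs)
    out = pairs.copy()
    out["r_discovery"] = r
    out["p_discovery"] = p
    out["n_obs"] = n
    dropped = out["r_discovery"].isna()
    if dropped.any():
        log.info("skipped %d pairs with zero-variance signal", int(dropped.sum()))
        out = out[~dropped].reset_index(drop=True)
    out["nominal"] = (out["p_discovery"] < p_threshold) & (
        out["r_discovery"].abs() > r_threshold
    )
    return out


def validate_links(
    links: pd.DataFrame,
    atac_norm: pd.DataFrame,
    scrna_norm: pd.DataFrame,
    r_threshold: float = 0.65,
) -> pd.DataFrame:
    """Validation in the unpaired layers (snATAC vs scRNA pseudobulk).

    ``validated`` requires sign(r_validation) == sign(r_discovery) and
    |r_validation| > 0.65 (strict).
    """
    r, p, _ = _pair_correlations(atac_norm, scrna_norm, links)
    out = links.copy()
    out["r_validation"] = r
    out["validated"] = (
        (np.sign(out["r_validation"]) == np.sign(out["r_discovery"]))
        & (out["r_validation"].abs() > r_threshold)
    ).fillna(False)
    return out


def link_density(links: pd.DataFrame) -> pd.DataFrame:
    """Descriptive links-per-kb per distance bin.

    Density = link count / (bin width in kb x number of genes with at
    least one candidate peak in that bin).
    """
    rows = []
    for name, lo, hi in DISTANCE_BINS:
        width_kb = (min(hi, 1_000_000) - lo) / 1_000
        sub = links[links["bin"] == name]
        n_genes = sub["gene_id"].nunique()
        n_links = int(sub["nominal"].sum()) if "nominal" in sub.columns else len(sub)
        density = n_links / (width_kb * n_genes) if n_genes else 0.0
        rows.append((name, lo, min(hi, 1_000_000), n_links, n_genes, density))
    return pd.DataFrame(
        rows, columns=["bin", "lo", "hi", "n_links", "n_genes", "links_per_kb"]
    )
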