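"""Genotype-dosage QTL scan near index SNVs.

For each index SNV, every feature within 1 Mb (gene TSS or peak
midpoint) is tested per (lineage, timepoint): Spearman rank correlation
(midrank ties, two-sided t-approximation p) between donors' normalized
pseudobulk signal and alt-allele dosage (0/1/2).  Bonferroni correction
multiplies by the number of tests performed within each (lineage,
modality).  Monomorphic SNVs are skipped and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_VALID_GT = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2}
_MISSING_GT = {"./.", ".", ""}


def encode_dosage(genotype: str | None) -> int | None:
    """Alt-allele count for a diploid genotype string.

    ``"0/0" -> 0``, ``"0/1"``/``"1/0" -> 1``, ``"1/1" -> 2``; missing
    (``"./."``) maps to ``None``.  Anything else is an error.
    """
    if genotype is None:
        return None
    gt = genotype.strip()
    if gt in _MISSING_GT:
        return None
    try:
        return _VALID_GT[gt]
    except KeyError:
        raise ValueError(f"unrecognized genotype {genotype!r}") from None


def _features_in_window(
    snv: pd.Series, genes: pd.DataFrame, peaks: pd.DataFrame, window: float
) -> dict[str, list[str]]:
    """Feature ids within `window` of the SNV, per modality class."""
    g = genes[(genes["chrom"] == snv["chrom"]) & (np.abs(genes["tss"] - snv["pos"]) <= window)]
    mids = (peaks["start"] + peaks["end"]) / 2.0
    p = peaks[(peaks["chrom"] == snv["chrom"]) & (np.abs(mids - snv["pos"]) <= window)]
    return {"gene": list(g["gene_id"]), "peak": list(p["peak_id"])}


def _spearman_vec(signal: np.ndarray, dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and t-approx p of each signal column against dosage."""
    n = len(dosage)
    ranks = stats.rankdata(signal, axis=0)
    dr = stats.rankdata(dosage)
    ranks = ranks - ranks.mean(axis=0)
    dr = dr - dr.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ranks * dr[:, None]).sum(axis=0) / (
            np.sqrt((ranks**2).sum(axis=0)) * np.sqrt((dr**2).sum())
        )
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, np.clip(p, np.finfo(float).tiny, 1.0)


def qtl_scan(
    genotypes: pd.DataFrame,
    normalized_by_modality: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    window: float = 1e6,
) -> pd.DataFrame:
    """Dosage-association scan over all (SNV, in-window feature) pairs.

    Parameters
    ----------
    genotypes
        snv_id, chrom, pos plus one dosage column per donor.
    normalized_by_modality
        Per-million pseudobulk signals keyed by modality (gene features
        for RNA layers, peak features for snATAC), MultiIndex
        (donor_id, timepoint, lineage).
    window
        Scan window around the SNV position, default 1 Mb.

    Returns
    -------
    DataFrame: snv_id, feature_id, modality, lineage, timepoint, rho, p,
    p_bonf, n_donors, with Bonferroni multiplier = number of tests within
    each (lineage, modality).
    """
    donor_cols = [c for c in genotypes.columns if c not in ("snv_id", "chrom", "pos")]
    rows = []
    for _, snv in genotypes.iterrows():
        dosage_all = snv[donor_cols].astype("Float64")
        present = dosage_all.dropna()
        if present.nunique() < 2:
            log.warning("SNV %s is monomorphic among genotyped donors; skipped", snv["snv_id"])
            continue
        windows = _features_in_window(snv, genes, peaks, window)
        for modality, norm in normalized_by_modality.items():
            feats = windows["peak" if modality == "snATAC" else "gene"]
            feats = [f for f in feats if f in norm.columns]
            if not feats:
                continue
            for (tp, lineage), sub in norm.groupby(level=["timepoint", "lineage"], sort=True):
                sub = sub.droplevel(["timepoint", "lineage"])
                donors = [d for d in sub.index if d in present.index]
                if len(donors) < 3:
                    continue
                dos = present.loc[donors].to_numpy(dtype=float)
                if len(np.unique(dos)) < 2:
                    continue
                sig = sub.loc[donors, feats].to_numpy(dtype=float)
                rho, p = _spearman_vec(sig, dos)
                for f, r_, p_ in zip(feats, rho, p):
                    rows.append(
                        (snv["snv_id"], f, modality, lineage, tp, r_, p_, len(donors))
                    )
    table = pd.DataFrame(
        rows,
        columns=["snv_id", "feature_id", "modality", "lineage", "timepoint", "rho", "p", "n_donors"],
    )
    if len(table):
        n_tests = table.groupby(["lineage", "modality"])["p"].transform("size")
        table["p_bonf"] = np.minimum(1.0, table["p"] * n_tests)
    else:
        table["p_bonf"] = pd.Series(dtype=float)
    return table[
        ["snv_id", "feature_id", "modality", "lineage", "timepoint", "rho", "p", "p_bonf", "n_donors"]
    ]


def overlap_with_differential(
    qtl_hits: pd.DataFrame,
    differential: pd.DataFrame,
    genotypes: pd.DataFrame,
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    window: float = 1e5,
) -> pd.DataFrame:
    """Per-locus overlap of QTL-associated and case-control features.

    For each SNV, lists the differential (significant) features within
    ``window`` and flags whether any QTL-associated feature at the locus
    is also case-control significant.

    ``qtl_hits`` should be pre-filtered to associated rows (e.g.
    ``p_bonf < 0.05``); ``differential`` rows are filtered on their
    ``significant`` flag.
    """
    sig = differential[differential["significant"]] if "significant" in differential.columns else differential
    sig_feats = set(sig["feature_id"])
    rows = []
    for _, snv in genotypes.iterrows():
        windows = _features_in_window(snv, genes, peaks, window)
        near = [f for f in windows["gene"] + windows["peak"] if f in sig_feats]
        qtl_feats = set(qtl_hits.loc[qtl_hits["snv_id"] == snv["snv_id"], "feature_id"])
        shared = sorted(qtl_feats & sig_feats)
        rows.append(
            {
                "snv_id": snv["snv_id"],
                "n_differential_near": len(near),
                "differential_near": ",".join(sorted(near)),
                "n_qtl_features": len(qtl_feats),
                "qtl_and_differential": ",".join(shared),
                "overlaps": bool(shared),
            }
        )
    return pd.DataFrame(rows)
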