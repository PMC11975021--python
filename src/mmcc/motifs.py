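"""Directional TF-motif representation test between case-up and
case-down differential peaks.

Per motif, occurrence (binary by default: >= 1 hit per peak) is compared
between the case-up and case-down peak sets with the same two-sided
Fisher exact implementation used by the differential module; the fold
change is the occurrence-rate ratio and motifs at nominal p < 0.01 are
flagged.
"""

from __future__ import annotations

import logging

import pandas as pd

from mmcc.differential import fisher_twosided_many, proportion_ratio

log = logging.getLogger(__name__)


def directional_motif_test(
    motif_hits: pd.DataFrame,
    up_peaks: set[str],
    down_peaks: set[str],
    alpha: float = 0.01,
    count_mode: str = "binary",
) -> pd.DataFrame:
    """2x2 motif-representation test per motif.

    Parameters
    ----------
    motif_hits
        Table with columns peak_id, motif_id (and n_hits, used when
        ``count_mode="hits"``).
    up_peaks, down_peaks
        Disjoint sets of differential peak ids (increased access in
        cases vs. in controls).
    alpha
        Nominal significance threshold for the ``significant`` flag.
    count_mode
        ``"binary"`` (default): a = up peaks containing the motif,
        b = up peaks without, c/d likewise for down peaks.  ``"hits"``:
        total hit counts replace peak counts.

    Motifs absent from both sets are skipped.
    """
    if up_peaks & down_peaks:
        raise ValueError("up and down peak sets must be disjoint")
    n_up, n_down = len(up_peaks), len(down_peaks)
    if n_up == 0 or n_down == 0:
        raise ValueError("both peak sets must be non-empty")
    hits = motif_hits[motif_hits["peak_id"].isin(up_peaks | down_peaks)]
    rows = []
    for motif, sub in hits.groupby("motif_id", sort=True):
        if count_mode == "binary":
            peaks_with = set(sub["peak_id"])
            a = len(peaks_with & up_peaks)
            c = len(peaks_with & down_peaks)
            b, d = n_up - a, n_down - c
        elif count_mode == "hits":
            a = int(sub.loc[sub["peak_id"].isin(up_peaks), "n_hits"].sum())
            c = int(sub.loc[sub["peak_id"].isin(down_peaks), "n_hits"].sum())
            b = int(
                motif_hits.loc[
                    motif_hits["peak_id"].isin(up_peaks) & (motif_hits["motif_id"] != motif),
                    "n_hits",
                ].sum()
            )
            d = int(
                motif_hits.loc[
                    motif_hits["peak_id"].isin(down_peaks) & (motif_hits["motif_id"] != motif),
                    "n_hits",
                ].sum()
            )
        else:
            raise ValueError(f"unknown count_mode {count_mode!r}")
        if a + c == 0:
            log.info("motif %s absent from both peak sets; skipped", motif)
            continue
        p = float(fisher_twosided_many([a], [b], [c], [d])[0])
        fold = float(proportion_ratio([a], [b], [c], [d])[0])
        rows.append((motif, a, b, c, d, fold, p, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["motif_id", "a", "b", "c", "d", "fold_change", "p", "significant"],
    )
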