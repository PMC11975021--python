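"""Cross-data-layer replication of case-control discoveries.

Each discovery (feature, lineage, timepoint, modality at q below
threshold) is checked against the orthogonal data layers:

* a gene discovered in snRNA at (g, L, T) can replicate in scRNA at
  (g, L, T), in snRNA at (g, L, T') for each other timepoint T', and in
  snATAC via any peak linked to g at (L, T);
* a gene discovered in scRNA symmetrically (snRNA same stratum, scRNA
  other timepoints, linked peaks);
* a peak discovered in snATAC replicates via snATAC at other timepoints
  or via its linked gene's expression in snRNA / scRNA at (L, T).

A layer replicates when the corresponding test reaches q < threshold
with the same direction; for linked features, concordance means the
accessibility and expression changes share sign.  A discovery counts as
*replicated* when the signal is present in at least ``min_layers`` data
layers including the discovery itself.
"""

from __future__ import annotations

import pandas as pd

from mmcc.types import TIMEPOINTS


def _result_lookup(table: pd.DataFrame, q_threshold: float) -> dict:
    """(feature, lineage, timepoint) -> direction for significant rows."""
    sig = table[table["q"] < q_threshold]
    return {
        (r.feature_id, r.lineage, r.timepoint): r.direction
        for r in sig.itertuples()
    }


def _link_maps(links: pd.DataFrame | None) -> tuple[dict, dict]:
    gene_to_peaks: dict[str, list[str]] = {}
    peak_to_genes: dict[str, list[str]] = {}
    if links is not None and len(links):
        use = links[links["nominal"]] if "nominal" in links.columns else links
        for r in use.itertuples():
            gene_to_peaks.setdefault(r.gene_id, []).append(r.peak_id)
            peak_to_genes.setdefault(r.peak_id, []).append(r.gene_id)
    return gene_to_peaks, peak_to_genes


def assess_replication(
    results_by_layer: dict[str, pd.DataFrame],
    links: pd.DataFrame | None = None,
    q_threshold: float = 0.10,
    min_layers: int = 2,
) -> pd.DataFrame:
    """Replication records for every discovery in every layer.

    Parameters
    ----------
    results_by_layer
        Differential tables keyed by modality.  A modality absent from
        the dict is marked untested for discoveries that would have
        queried it.
    links
        Peak-gene link table (``peak_id``, ``gene_id``; rows flagged
        ``nominal`` are used if the column exists).
    q_threshold, min_layers
        Significance threshold per layer and the minimum number of data
        layers (including the discovery) for the ``replicated`` flag.

    Returns
    -------
    DataFrame with one row per discovery: feature_id, lineage, timepoint,
    modality, direction, layers_tested, layers_replicated, n_replicating,
    replicated.
    """
    lookups = {m: _result_lookup(t, q_threshold) for m, t in results_by_layer.items()}
    gene_to_peaks, peak_to_genes = _link_maps(links)
    rows = []
    for modality, table in results_by_layer.items():
        discoveries = table[table["q"] < q_threshold]
        for disc in discoveries.itertuples():
            feat, lineage, tp, direction = (
                disc.feature_id, disc.lineage, disc.timepoint, disc.direction,
            )
            layers: list[tuple[str, list[tuple[str, str, str, str]]]] = []
            if modality in ("snRNA", "scRNA"):
                other_rna = "scRNA" if modality == "snRNA" else "snRNA"
                layers.append((f"{other_rna}@{tp}", [(other_rna, feat, lineage, tp)]))
                for tp2 in TIMEPOINTS:
                    if tp2 != tp:
                        layers.append((f"{modality}@{tp2}", [(modality, feat, lineage, tp2)]))
                linked = gene_to_peaks.get(feat, [])
                layers.append(
                    (f"snATAC-linked@{tp}", [("snATAC", p, lineage, tp) for p in linked])
                )
            else:
                for tp2 in TIMEPOINTS:
                    if tp2 != tp:
                        layers.append((f"snATAC@{tp2}", [("snATAC", feat, lineage, tp2)]))
                linked = peak_to_genes.get(feat, [])
                for rna in ("snRNA", "scRNA"):
                    layers.append(
                        (f"{rna}-linked@{tp}", [(rna, g, lineage, tp) for g in linked])
                    )
            tested, replicated = [], []
            for name, probes in layers:
                probe_layers = {pl for pl, *_ in probes}
                if any(pl not in lookups for pl in probe_layers):
                    continue  # layer table missing: untested, not failed
                tested.append(name)
                for pl, f2, l2, t2 in probes:
                    hit = lookups[pl].get((f2, l2, t2))
                    if hit is not None and hit == direction:
                        replicated.append(name)
                        break
            n_rep = len(replicated)
            rows.append(
                {
                    "feature_id": feat,
                    "lineage": lineage,
                    "timepoint": tp,
                    "modality": modality,
                    "direction": direction,
                    "layers_tested": ",".join(tested),
                    "layers_replicated": ",".join(replicated),
                    "n_replicating": n_rep,
                    "replicated": n_rep >= min_layers - 1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "lineage", "timepoint", "modality", "direction",
            "layers_tested", "layers_replicated", "n_replicating", "replicated",
        ],
    )


def replicated_sets(records: pd.DataFrame) -> dict[tuple[str, str, str], set[str]]:
    """Replicated-signal feature sets keyed by (lineage, timepoint, direction)."""
    out: dict[tuple[str, str, str], set[str]] = {}
    rep = records[records["replicated"]]
    for r in rep.itertuples():
        out.setdefault((r.lineage, r.timepoint, r.direction), set()).add(r.feature_id)
    return out
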