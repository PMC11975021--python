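"""Pseudobulk aggregation and per-million normalization.

Counts are summed over cells within each (donor, timepoint, parent
lineage) key; normalized signal is reads-per-million within the key, i.e.
each feature's total divided by the key's total over all features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from mmcc.lineage import collapse_lineage
from mmcc.types import BundleError, CountLayer, Pseudobulk

log = logging.getLogger(__name__)


def make_pseudobulk(
    layer: CountLayer,
    annotations: pd.DataFrame,
    lineage_map: dict[str, str] | None = None,
) -> Pseudobulk:
    """Aggregate a count layer to (donor, timepoint, lineage) read totals.

    Every cell in the layer must have exactly one annotation row (matched
    on ``cell_id`` with ``layer == layer.modality``); every sub-lineage
    label must collapse under ``lineage_map``.  Read totals are conserved:
    the table's grand total equals the matrix's grand total.

    Keys with no cells simply do not appear (and are logged).
    """
    ann = annotations[annotations["layer"] == layer.modality]
    ann = ann.set_index("cell_id")
    missing = [c for c in layer.cell_ids if c not in ann.index]
    if missing:
        raise BundleError(
            f"layer {layer.modality}: no annotation for cells {missing[:5]}"
        )
    ann = ann.loc[layer.cell_ids]
    parents = ann["sublineage_label"].map(lambda s: collapse_lineage(s, lineage_map))

    keys = pd.MultiIndex.from_arrays(
        [ann["donor_id"], ann["timepoint"], parents],
        names=["donor_id", "timepoint", "lineage"],
    )
    codes, uniq = keys.factorize(sort=True)
    # cells x keys indicator, so totals = indicator.T @ matrix in one sparse op
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(layer.n_cells, len(uniq)),
    )
    totals = np.asarray((ind.T @ layer.matrix).todense())
    table = pd.DataFrame(totals.astype(np.int64), index=uniq, columns=layer.feature_ids)
    table.index.names = ["donor_id", "timepoint", "lineage"]
    return Pseudobulk(modality=layer.modality, totals=table)


def normalize_per_million(pb: Pseudobulk) -> pd.DataFrame:
    """Reads-per-million normalized signals; rows sum to 1e6.

    Zero-total keys are flagged (logged) and excluded: their normalized
    signal is undefined.
    """
    key_totals = pb.key_totals()
    zero = key_totals[key_totals == 0]
    for key in zero.index:
        log.warning("pseudobulk key %s has zero total reads; excluded", key)
    return pb.per_million()
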