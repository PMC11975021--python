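"""Core data containers and controlled vocabularies.

The pipeline operates on annotated count matrices (one per data layer),
sample metadata for matched case-control pairs, a peak interval table, a
gene model table, and a genotype dosage table.  Tabular data is held in
pandas DataFrames with the column contracts documented here; count
matrices are scipy sparse matrices wrapped in :class:`CountLayer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: The three data layers (modalities).  snRNA and snATAC come from the same
#: multiome nuclei; scRNA is an independent capture from the same donors.
MODALITIES = ("snRNA", "scRNA", "snATAC")

#: Longitudinal sampling: before seroconversion, after seroconversion, and
#: close to clinical diagnosis.
TIMEPOINTS = ("T1", "T2", "T3")

#: The five collapsed parent immune lineages.
LINEAGES = ("Monocyte", "B", "CD4T", "CD8T", "NK")

#: Autoantibody-order endotype labels (mutually exclusive; controls = none).
ENDOTYPES = (
    "IAA_first_strict",
    "IAA_first_loose",
    "GADA_first_strict",
    "GADA_first_loose",
    "other",
    "none",
)

#: Columns of a cell annotation table.
CELL_COLUMNS = ("cell_id", "donor_id", "timepoint", "sublineage_label", "layer")

#: Columns of a sample (donor) metadata table.
SAMPLE_COLUMNS = ("donor_id", "status", "pair_id", "endotype", "seroconversion_age")


class BundleError(ValueError):
    """Raised when a data bundle violates a structural invariant."""


@dataclass
class CountLayer:
    """Sparse non-negative integer count matrix for one modality.

    Parameters
    ----------
    modality
        One of :data:`MODALITIES`.
    matrix
        ``cells x features`` sparse matrix of non-negative integer counts.
    cell_ids, feature_ids
        Unique identifiers for rows and columns.
    """

    modality: str
    matrix: sp.spmatrix
    cell_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise BundleError(f"unknown modality {self.modality!r}")
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise BundleError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise BundleError("duplicate cell_ids in layer")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise BundleError("duplicate feature_ids in layer")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise BundleError("negative counts in layer")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_anndata(self):
        """Return an :class:`anndata.AnnData` view of this layer."""
        import anndata as ad

        return ad.AnnData(
            X=self.matrix.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.feature_ids, name="feature_id")),
        )


@dataclass
class Pseudobulk:
    """Per (donor, timepoint, lineage) aggregated feature read totals.

    ``totals`` is a DataFrame with a MultiIndex ``(donor_id, timepoint,
    lineage)`` and one integer column per feature.  Totals conserve reads:
    each row is the column sum of the source matrix over the cells in that
    key.
    """

    modality: str
    totals: pd.DataFrame

    def key_totals(self) -> pd.Series:
        """Total reads per (donor, timepoint, lineage) key."""
        return self.totals.sum(axis=1)

    def per_million(self) -> pd.DataFrame:
        """Reads-per-million normalized signals (rows sum to 1e6).

        Keys with zero total reads are dropped (their normalized signal is
        undefined and they are excluded downstream).
        """
        totals = self.key_totals()
        keep = totals > 0
        t = self.totals.loc[keep]
        return t.mul(1e6 / totals[keep], axis=0)


def validate_bundle_tables(
    cells: pd.DataFrame, samples: pd.DataFrame, *, layers: dict[str, CountLayer] | None = None
) -> None:
    """Check cross-table invariants of a bundle's metadata.

    Raises :class:`BundleError` naming the offending record on the first
    violation found.
    """
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise BundleError(f"cell table missing column {col!r}")
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise BundleError(f"sample table missing column {col!r}")
    bad_tp = set(cells["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise BundleError(f"unknown timepoints {sorted(bad_tp)}")
    unknown_donor = set(cells["donor_id"]) - set(samples["donor_id"])
    if unknown_donor:
        raise BundleError(f"cells reference donors absent from samples: {sorted(unknown_donor)}")
    # each pair_id: exactly one case and one control
    for pair_id, grp in samples.groupby("pair_id"):
        statuses = sorted(grp["status"])
        if statuses != ["case", "control"]:
            raise BundleError(f"pair {pair_id!r} is not one case + one control: {statuses}")
    ctrl = samples[samples["status"] == "control"]
    bad = ctrl[ctrl["endotype"] != "none"]
    if len(bad):
        raise BundleError(f"controls with non-none endotype: {sorted(bad['donor_id'])}")
    if layers:
        for name, layer in layers.items():
            ann = cells[cells["layer"] == name]
            missing = set(layer.cell_ids) - set(ann["cell_id"])
            if missing:
                raise BundleError(
                    f"layer {name}: cells without annotation: {sorted(missing)[:5]}"
                )
            if ann["cell_id"].duplicated().any():
                dup = ann.loc[ann["cell_id"].duplicated(), "cell_id"].iloc[0]
                raise BundleError(f"layer {name}: duplicate annotation for cell {dup!r}")


def validate_peaks(peaks: pd.DataFrame) -> None:
    """Check the peak table invariant: valid intervals, unique ids, sorted."""
    if peaks["peak_id"].duplicated().any():
        dup = peaks.loc[peaks["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise BundleError(f"duplicate peak_id {dup!r}")
    bad = peaks[peaks["start"] >= peaks["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise BundleError(
            f"peak {row['peak_id']!r}: start {row['start']} >= end {row['end']}"
        )
    srt = peaks.sort_values(["chrom", "start"], kind="stable")
    if not (srt.index == peaks.index).all():
        raise BundleError("peak table is not sorted by (chrom, start)")


def peak_midpoints(peaks: pd.DataFrame) -> np.ndarray:
    """Midpoint of each 0-based half-open peak interval."""
    return (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0
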