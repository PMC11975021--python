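"""Bundle directory reading/writing.

A *bundle* is a directory of plain-text files describing one cohort:

* ``<modality>/matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` per layer
  (MatrixMarket, cells x features)
* ``cells.tsv`` — cell annotations (cell_id, donor_id, timepoint,
  sublineage_label, layer)
* ``samples.tsv`` — donor metadata (donor_id, status, pair_id, endotype,
  seroconversion_age)
* ``peaks.bed`` — BED3+name, 0-based half-open, sorted by (chrom, start)
* ``genes.tsv`` — gene_id, chrom, tss, strand
* ``genotypes.tsv`` — snv_id, chrom, pos, then one alt-allele dosage
  column (0/1/2 or ``.``) per donor
* optionally ``motif_hits.tsv`` (peak_id, motif_id, n_hits) and
  ``truth.json`` (planted ground truth from the simulator)

Round-trip write -> read is lossless for counts and metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from mmcc.types import (
    BundleError,
    CountLayer,
    MODALITIES,
    validate_bundle_tables,
    validate_peaks,
)


@dataclass
class Bundle:
    """In-memory cohort bundle: count layers plus all metadata tables."""

    layers: dict[str, CountLayer]
    cells: pd.DataFrame
    samples: pd.DataFrame
    peaks: pd.DataFrame
    genes: pd.DataFrame
    genotypes: pd.DataFrame
    motif_hits: pd.DataFrame | None = None
    truth: dict | None = None
    extras: dict = field(default_factory=dict)

    def donor_ids(self) -> list[str]:
        return list(self.samples["donor_id"])

    def validate(self) -> None:
        validate_bundle_tables(self.cells, self.samples, layers=self.layers)
        validate_peaks(self.peaks)
        if self.genes["gene_id"].duplicated().any():
            raise BundleError("duplicate gene_id in gene table")
        if (self.genes["tss"] < 0).any():
            raise BundleError("negative TSS position in gene table")
        dosage_cols = [c for c in self.genotypes.columns if c not in ("snv_id", "chrom", "pos")]
        vals = self.genotypes[dosage_cols].to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise BundleError("genotype dosages must be 0/1/2 or missing")


def _write_layer(path: Path, layer: CountLayer) -> None:
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(layer.matrix.astype(np.int64)))
    pd.Series(layer.feature_ids).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(layer.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)


def _read_layer(path: Path, modality: str) -> CountLayer:
    matrix = sp.csr_matrix(mmread(str(path / "matrix.mtx"))).astype(np.int64)
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    return CountLayer(modality=modality, matrix=matrix, cell_ids=cells, feature_ids=features)


def read_peaks_bed(path: Path) -> pd.DataFrame:
    """Parse a BED3+name peak file, reporting the line number on errors."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BundleError(f"{path}:{lineno}: expected BED3+name, got {line!r}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise BundleError(
                    f"{path}:{lineno}: invalid interval start={start} >= end={end}"
                )
            rows.append((name, chrom, start, end))
    peaks = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    validate_peaks(peaks)
    return peaks


def write_bundle(bundle: Bundle, path: str | Path) -> Path:
    """Write a bundle directory (deterministic formatting)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, layer in bundle.layers.items():
        _write_layer(path / name, layer)
    bundle.cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    bundle.samples.to_csv(path / "samples.tsv", sep="\t", index=False)
    bundle.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        path / "peaks.bed", sep="\t", index=False, header=False
    )
    bundle.genes.to_csv(path / "genes.tsv", sep="\t", index=False)
    bundle.genotypes.to_csv(path / "genotypes.tsv", sep="\t", index=False, na_rep=".")
    if bundle.motif_hits is not None:
        bundle.motif_hits.to_csv(path / "motif_hits.tsv", sep="\t", index=False)
    if bundle.truth is not None:
        with open(path / "truth.json", "w") as fh:
            json.dump(bundle.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return path


def read_bundle(path: str | Path, validate: bool = True) -> Bundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    layers = {m: _read_layer(path / m, m) for m in MODALITIES if (path / m).is_dir()}
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str)
    samples = pd.read_csv(
        path / "samples.tsv",
        sep="\t",
        dtype={"donor_id": str, "status": str, "pair_id": str, "endotype": str},
    )
    peaks = read_peaks_bed(path / "peaks.bed")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", dtype={"gene_id": str, "chrom": str})
    genotypes = pd.read_csv(path / "genotypes.tsv", sep="\t", na_values=["."])
    dosage_cols = [c for c in genotypes.columns if c not in ("snv_id", "chrom", "pos")]
    genotypes[dosage_cols] = genotypes[dosage_cols].astype("Int64")
    motif_hits = None
    if (path / "motif_hits.tsv").exists():
        motif_hits = pd.read_csv(path / "motif_hits.tsv", sep="\t", dtype={"peak_id": str, "motif_id": str})
    truth = None
    if (path / "truth.json").exists():
        with open(path / "truth.json") as fh:
            truth = json.load(fh)
    bundle = Bundle(
        layers=layers,
        cells=cells,
        samples=samples,
        peaks=peaks,
        genes=genes,
        genotypes=genotypes,
        motif_hits=motif_hits,
        truth=truth,
    )
    if validate:
        bundle.validate()
    return bundle
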