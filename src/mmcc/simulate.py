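"""Synthetic longitudinal multi-layer cohort generator with planted truth.

The generator emulates the structure of a matched case-control cohort
profiled at three time points in three data layers: multiome nuclei
(snRNA + snATAC drawn from the same nuclei) and an orthogonal scRNA
capture from the same donors.  Per-cell counts follow a gamma-mixed
multinomial: each cell draws a Poisson library size and allocates reads
over features with probabilities proportional to the (donor, timepoint,
lineage) rate vector, optionally perturbed per cell by gamma noise with
variance ``overdispersion`` (at 0 the model is pure multinomial, where
the pooled-read Fisher test is approximately calibrated).

Planted structure, recorded in :class:`SimTruth`:

* differential effects — fold changes applied to case donors' rates in a
  given (lineage, timepoint), optionally restricted to an autoantibody
  endotype subgroup;
* peak-gene links — a shared standard-normal latent per (donor,
  timepoint, lineage) multiplies both the peak and the gene rate via
  ``exp(coef * z - coef^2 / 2)``, inducing positive cross-modality
  correlation in every layer;
* dosage QTLs — a per-allele fold applied as ``fold ** dosage``;
* motif hits — planted preferentially in case-up differential peaks so
  the directional motif test has signal.

Baseline feature abundances are drawn once per cohort from a log-normal
distribution and shared across lineages; lineage identity enters through
cell-type proportions only, keeping non-planted features exchangeable
between strata (the property the null-calibration tests rely on).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from mmcc.lineage import LINEAGE_SUBLABELS
from mmcc.types import CountLayer, LINEAGES, TIMEPOINTS
from mmcc.io import Bundle

# Endotype mix mirroring the study cohort: 21/49 IAA-first strict,
# 17/49 IAA-first loose, 8/49 GADA-first strict, 3/49 GADA-first loose.
DEFAULT_ENDOTYPE_FRACTIONS = {
    "IAA_first_strict": 21 / 49,
    "IAA_first_loose": 17 / 49,
    "GADA_first_strict": 8 / 49,
    "GADA_first_loose": 3 / 49,
}


@dataclass
class PlantedEffect:
    """A case-vs-control fold change on one feature in one stratum."""

    feature_id: str
    lineage: str
    timepoint: str
    log2fc: float  # positive = up in cases
    endotype: str | None = None  # e.g. "GADA_first" restricts to that subgroup


@dataclass
class PlantedLink:
    """A peak-gene pair sharing a latent activity across observations."""

    peak_id: str
    gene_id: str
    coef: float  # scale of the shared log-normal latent


@dataclass
class PlantedQtl:
    """A feature whose rate scales multiplicatively with allele dosage."""

    snv_id: str
    feature_id: str
    allele_fold: float  # rate multiplier per alt allele


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults give a desk-scale cohort (10 matched pairs, 200 genes, 300
    peaks, 100 cells per donor/timepoint/layer) that runs the full
    pipeline in well under a minute.
    """

    n_pairs: int = 10
    n_genes: int = 200
    n_peaks: int = 300
    cells_per_sample: int = 100
    lineage_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "Monocyte": 0.25, "B": 0.15, "CD4T": 0.30, "CD8T": 0.18, "NK": 0.12,
        }
    )
    rna_reads_per_cell: int = 800
    atac_reads_per_cell: int = 1500
    baseline_sigma: float = 1.2  # log-normal sigma of baseline feature abundances
    overdispersion: float = 0.0
    effects: list[PlantedEffect] = field(default_factory=list)
    links: list[PlantedLink] = field(default_factory=list)
    qtls: list[PlantedQtl] = field(default_factory=list)
    n_snvs: int = 8
    snv_maf: float = 0.3
    endotype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENDOTYPE_FRACTIONS)
    )
    n_motifs: int = 10
    motif_background_rate: float = 0.10
    motif_planted_rate: float = 0.60
    planted_motif: str = "M001"
    chroms: tuple[str, ...] = ("chr1", "chr2")
    gene_spacing: int = 50_000
    peak_spacing: int = 33_000
    peak_width: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        # accept plain dicts (e.g. from YAML / JSON round-trips)
        self.effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e) for e in self.effects
        ]
        self.links = [
            l if isinstance(l, PlantedLink) else PlantedLink(**l) for l in self.links
        ]
        self.qtls = [q if isinstance(q, PlantedQtl) else PlantedQtl(**q) for q in self.qtls]
        self.chroms = tuple(self.chroms)

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def peak_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_peaks)]

    def validate(self) -> None:
        props = np.array([self.lineage_proportions[ln] for ln in LINEAGES])
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("lineage proportions must sum to 1")
        genes, peaks = set(self.gene_ids()), set(self.peak_ids())
        for eff in self.effects:
            if eff.feature_id not in genes and eff.feature_id not in peaks:
                raise ValueError(f"planted effect on unknown feature {eff.feature_id!r}")
            if eff.lineage not in LINEAGES or eff.timepoint not in TIMEPOINTS:
                raise ValueError(f"planted effect in unknown stratum {eff}")
        for link in self.links:
            if link.peak_id not in peaks or link.gene_id not in genes:
                raise ValueError(f"planted link on unknown features {link}")
        for qtl in self.qtls:
            if qtl.feature_id not in genes and qtl.feature_id not in peaks:
                raise ValueError(f"planted QTL on unknown feature {qtl.feature_id!r}")


@dataclass
class SimTruth:
    """Ground truth actually used by a simulated cohort."""

    effects: list[PlantedEffect]
    links: list[PlantedLink]
    qtls: list[PlantedQtl]
    endotypes: dict[str, str]  # donor_id -> endotype label
    planted_motif: str | None = None

    def to_json(self) -> dict:
        return {
            "effects": [asdict(e) for e in self.effects],
            "links": [asdict(x) for x in self.links],
            "qtls": [asdict(q) for q in self.qtls],
            "endotypes": dict(sorted(self.endotypes.items())),
            "planted_motif": self.planted_motif,
        }


def snv_position(config: SimConfig, snv_id: str) -> tuple[str, str, int]:
    """Deterministic (snv_id, chrom, pos) placement, spread evenly over
    the gene span of the toy genome so 1 Mb windows stay populated."""
    i = int(snv_id.lstrip("rs"))
    n_chrom = len(config.chroms)
    chrom = config.chroms[i % n_chrom]
    span = 10_000 + max(config.n_genes // n_chrom - 1, 1) * config.gene_spacing
    n_per_chrom = max(-(-config.n_snvs // n_chrom), 1)
    pos = int(span * (i // n_chrom + 1) / (n_per_chrom + 1))
    return snv_id, chrom, pos


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Deterministic integer allocation of `total` by `fractions`."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _feature_tables(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene model and peak interval tables laid out on the toy genome."""
    genes, peaks = [], []
    n_chrom = len(config.chroms)
    for i, gid in enumerate(config.gene_ids()):
        chrom = config.chroms[i % n_chrom]
        tss = 10_000 + (i // n_chrom) * config.gene_spacing
        genes.append((gid, chrom, tss, "+" if i % 2 == 0 else "-"))
    for i, pid in enumerate(config.peak_ids()):
        chrom = config.chroms[i % n_chrom]
        start = 5_000 + (i // n_chrom) * config.peak_spacing
        peaks.append((pid, chrom, start, start + config.peak_width))
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss", "strand"])
    peak_df = (
        pd.DataFrame(peaks, columns=["peak_id", "chrom", "start", "end"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    return gene_df, peak_df


def _assign_endotypes(case_ids: list[str], fractions: dict[str, float], rng) -> dict[str, str]:
    labels = list(fractions)
    counts = _largest_remainder(
        len(case_ids), np.array([fractions[k] for k in labels], dtype=float)
    )
    pool = [lab for lab, n in zip(labels, counts) for _ in range(n)]
    pool += ["other"] * (len(case_ids) - len(pool))
    order = rng.permutation(len(case_ids))
    return {case_ids[i]: pool[j] for j, i in enumerate(order)}


def _draw_cells(rng, n_cells: int, depth: int, rates: np.ndarray, overdispersion: float):
    """Count matrix for one (donor, timepoint, lineage) cell group."""
    libs = rng.poisson(depth, size=n_cells)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        noise = rng.gamma(shape, overdispersion, size=(n_cells, len(rates)))
        probs = rates * noise
        probs /= probs.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(libs[i], probs[i]) for i in range(n_cells)])
    else:
        counts = rng.multinomial(libs, rates / rates.sum())
    return counts


def simulate_cohort(config: SimConfig) -> tuple[Bundle, SimTruth]:
    """Simulate a cohort bundle plus its ground truth.

    The same (config, seed) always yields byte-identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_ids()
    peak_ids = config.peak_ids()
    genes_df, peaks_df = _feature_tables(config)

    case_ids = [f"D{i:03d}C" for i in range(config.n_pairs)]
    ctrl_ids = [f"D{i:03d}N" for i in range(config.n_pairs)]
    endotypes = _assign_endotypes(case_ids, config.endotype_fractions, rng)
    samples = pd.DataFrame(
        {
            "donor_id": case_ids + ctrl_ids,
            "status": ["case"] * config.n_pairs + ["control"] * config.n_pairs,
            "pair_id": [f"PAIR{i:03d}" for i in range(config.n_pairs)] * 2,
            "endotype": [endotypes[d] for d in case_ids] + ["none"] * config.n_pairs,
            "seroconversion_age": np.concatenate(
                [np.round(rng.uniform(0.7, 7.0, size=config.n_pairs), 2),
                 np.full(config.n_pairs, np.nan)]
            ),
        }
    ).sort_values("donor_id", kind="stable").reset_index(drop=True)
    donors = list(samples["donor_id"])

    # genotype dosages per donor; redraw any monomorphic SNV
    snv_ids = [f"rs{i:04d}" for i in range(config.n_snvs)]
    dosages = {}
    for snv in snv_ids:
        for _ in range(100):
            d = rng.binomial(2, config.snv_maf, size=len(donors))
            if len(np.unique(d)) > 1:
                break
        dosages[snv] = d
    # SNVs placed mid-genome so 1 Mb windows catch features
    snv_pos = [snv_position(config, snv) for snv in snv_ids]
    genotypes = pd.DataFrame(snv_pos, columns=["snv_id", "chrom", "pos"])
    for j, donor in enumerate(donors):
        genotypes[donor] = [int(dosages[s][j]) for s in snv_ids]
    donor_dosage = {
        (snv, donor): dosages[snv][j] for snv in snv_ids for j, donor in enumerate(donors)
    }

    # baseline abundances, shared across lineages and timepoints
    gene_base = np.exp(rng.normal(0.0, config.baseline_sigma, size=config.n_genes))
    peak_base = np.exp(rng.normal(0.0, config.baseline_sigma, size=config.n_peaks))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    peak_index = {p: i for i, p in enumerate(peak_ids)}
    # Planted differential features get fixed baseline weights w = 1/|fold-1|
    # so each planted effect moves exactly one unit of rate mass: with equal
    # numbers of up and down effects the case rate vector renormalizes
    # without displacing non-planted features, in the full cohort and in
    # every endotype subgroup alike.
    for eff in config.effects:
        weight = 1.0 / abs(2.0 ** eff.log2fc - 1.0)
        if eff.feature_id in gene_index:
            gene_base[gene_index[eff.feature_id]] = weight
        else:
            peak_base[peak_index[eff.feature_id]] = weight

    # shared link latents: one N(0,1) per (link, donor, timepoint, lineage)
    link_z = rng.standard_normal((len(config.links), len(donors), len(TIMEPOINTS), len(LINEAGES)))
    donor_pos = {d: i for i, d in enumerate(donors)}
    tp_pos = {t: i for i, t in enumerate(TIMEPOINTS)}
    lin_pos = {ln: i for i, ln in enumerate(LINEAGES)}
    status = dict(zip(samples["donor_id"], samples["status"]))

    def in_endotype(donor: str, tag: str | None) -> bool:
        if tag is None:
            return True
        lab = endotypes.get(donor, "none")
        return lab == tag or lab.startswith(tag + "_") or lab == tag + "_strict" or lab == tag + "_loose"

    def rate_vectors(donor: str, tp: str, lineage: str) -> tuple[np.ndarray, np.ndarray]:
        g = gene_base.copy()
        p = peak_base.copy()
        if status[donor] == "case":
            for eff in config.effects:
                if eff.lineage == lineage and eff.timepoint == tp and in_endotype(donor, eff.endotype):
                    fold = 2.0 ** eff.log2fc
                    if eff.feature_id in gene_index:
                        g[gene_index[eff.feature_id]] *= fold
                    else:
                        p[peak_index[eff.feature_id]] *= fold
        for qtl in config.qtls:
            dose = donor_dosage[(qtl.snv_id, donor)]
            if dose:
                fold = qtl.allele_fold ** dose
                if qtl.feature_id in gene_index:
                    g[gene_index[qtl.feature_id]] *= fold
                else:
                    p[peak_index[qtl.feature_id]] *= fold
        for li, link in enumerate(config.links):
            z = link_z[li, donor_pos[donor], tp_pos[tp], lin_pos[lineage]]
            mult = np.exp(link.coef * z - link.coef**2 / 2)
            g[gene_index[link.gene_id]] *= mult
            p[peak_index[link.peak_id]] *= mult
        return g, p

    lineage_counts = _largest_remainder(
        config.cells_per_sample,
        np.array([config.lineage_proportions[ln] for ln in LINEAGES]),
    )
    sublabel_choices = {ln: LINEAGE_SUBLABELS[ln] for ln in LINEAGES}

    layer_blocks: dict[str, list[np.ndarray]] = {m: [] for m in ("snRNA", "scRNA", "snATAC")}
    layer_cells: dict[str, list[tuple]] = {m: [] for m in ("snRNA", "scRNA", "snATAC")}

    for donor in donors:
        for tp in TIMEPOINTS:
            for ln, n_cells in zip(LINEAGES, lineage_counts):
                if n_cells == 0:
                    continue
                g_rate, p_rate = rate_vectors(donor, tp, ln)
                subs_nuc = rng.choice(sublabel_choices[ln], size=n_cells)
                subs_sc = rng.choice(sublabel_choices[ln], size=n_cells)
                snrna = _draw_cells(rng, n_cells, config.rna_reads_per_cell, g_rate, config.overdispersion)
                snatac = _draw_cells(rng, n_cells, config.atac_reads_per_cell, p_rate, config.overdispersion)
                scrna = _draw_cells(rng, n_cells, config.rna_reads_per_cell, g_rate, config.overdispersion)
                base = f"{donor}_{tp}_{ln}"
                nuc_ids = [f"{base}_N{i:03d}" for i in range(n_cells)]
                sc_ids = [f"{base}_C{i:03d}" for i in range(n_cells)]
                layer_blocks["snRNA"].append(snrna)
                layer_blocks["snATAC"].append(snatac)
                layer_blocks["scRNA"].append(scrna)
                layer_cells["snRNA"] += [
                    (cid, donor, tp, sub, "snRNA") for cid, sub in zip(nuc_ids, subs_nuc)
                ]
                layer_cells["snATAC"] += [
                    (cid, donor, tp, sub, "snATAC") for cid, sub in zip(nuc_ids, subs_nuc)
                ]
                layer_cells["scRNA"] += [
                    (cid, donor, tp, sub, "scRNA") for cid, sub in zip(sc_ids, subs_sc)
                ]

    layers = {}
    cell_rows = []
    for modality in ("snRNA", "scRNA", "snATAC"):
        matrix = sp.csr_matrix(np.vstack(layer_blocks[modality]).astype(np.int64))
        cells = layer_cells[modality]
        layers[modality] = CountLayer(
            modality=modality,
            matrix=matrix,
            cell_ids=[c[0] for c in cells],
            feature_ids=gene_ids if modality != "snATAC" else peak_ids,
        )
        cell_rows += cells
    cells_df = pd.DataFrame(
        cell_rows, columns=["cell_id", "donor_id", "timepoint", "sublineage_label", "layer"]
    )

    motif_hits = _plant_motif_hits(config, peak_ids, rng)

    truth = SimTruth(
        effects=list(config.effects),
        links=list(config.links),
        qtls=list(config.qtls),
        endotypes=endotypes,
        planted_motif=config.planted_motif
        if any(e.log2fc > 0 and e.feature_id in peak_index for e in config.effects)
        else None,
    )
    bundle = Bundle(
        layers=layers,
        cells=cells_df,
        samples=samples,
        peaks=peaks_df,
        genes=genes_df,
        genotypes=genotypes,
        motif_hits=motif_hits,
        truth=truth.to_json(),
    )
    return bundle, truth


def _plant_motif_hits(config: SimConfig, peak_ids: list[str], rng) -> pd.DataFrame:
    """Peak x motif hit table; the planted motif is enriched in case-up peaks."""
    motif_ids = [f"M{i:03d}" for i in range(1, config.n_motifs + 1)]
    up_peaks = {
        e.feature_id
        for e in config.effects
        if e.log2fc > 0 and e.feature_id in set(peak_ids)
    }
    rows = []
    for pid in peak_ids:
        for mid in motif_ids:
            rate = (
                config.motif_planted_rate
                if (mid == config.planted_motif and pid in up_peaks)
                else config.motif_background_rate
            )
            if rng.random() < rate:
                rows.append((pid, mid, 1 + rng.poisson(0.3)))
    return pd.DataFrame(rows, columns=["peak_id", "motif_id", "n_hits"])


def simulate_null(config: SimConfig) -> tuple[Bundle, SimTruth]:
    """Simulate with all planted effect/link/QTL lists emptied."""
    import dataclasses

    null_config = dataclasses.replace(config, effects=[], links=[], qtls=[])
    return simulate_cohort(null_config)


def default_recovery_config(
    seed: int = 0, n_pairs: int = 20, gada_specific: bool = False
) -> SimConfig:
    """Recovery study conditions: planted 2-fold Monocyte-T1 effects,
    strong links, and dosage QTLs.

    20 gene effects in Monocyte at T1 (10 up / 10 down), 20 peak effects
    likewise, 10 peak-gene links with a strong shared latent, and 5
    dosage QTLs.  With ``gada_specific`` every other gene effect is
    restricted to the GADA-first case subgroup (the endotype-design
    conditions; see :func:`default_endotype_config`).
    """
    config = SimConfig(seed=seed, n_pairs=n_pairs)
    gene_ids = config.gene_ids()
    peak_ids = config.peak_ids()
    effects: list[PlantedEffect] = []
    for i in range(20):
        sign = 1.0 if i < 10 else -1.0
        endo = "GADA_first" if gada_specific and i % 2 == 1 else None
        effects.append(
            PlantedEffect(gene_ids[i], "Monocyte", "T1", sign * 1.0, endotype=endo)
        )
    for i in range(20):
        sign = 1.0 if i < 10 else -1.0
        effects.append(PlantedEffect(peak_ids[i], "Monocyte", "T1", sign * 1.0))
    genes_df, peaks_df = _feature_tables(config)
    tss = dict(zip(genes_df["gene_id"], zip(genes_df["chrom"], genes_df["tss"])))
    mids = dict(
        zip(peaks_df["peak_id"], zip(peaks_df["chrom"], (peaks_df["start"] + peaks_df["end"]) / 2))
    )
    links: list[PlantedLink] = []
    gi = 40  # keep link features clear of DE features
    for pid in peak_ids[40:]:
        if len(links) == 10:
            break
        pchrom, pmid = mids[pid]
        for gid in gene_ids[gi:]:
            gchrom, gtss = tss[gid]
            if gchrom == pchrom and abs(pmid - gtss) <= 1e6:
                links.append(PlantedLink(pid, gid, coef=1.0))
                gi = gene_ids.index(gid) + 1
                break
    # QTL targets: nearest free gene (first 3 SNVs) or peak (next 2) to the
    # SNV on the same chromosome, so the scan window always contains them
    qtls: list[PlantedQtl] = []
    used = {e.feature_id for e in effects} | {l.peak_id for l in links} | {l.gene_id for l in links}
    for i in range(5):
        snv_id, chrom, pos = snv_position(config, f"rs{i:04d}")
        table = genes_df if i < 3 else peaks_df
        col = "gene_id" if i < 3 else "peak_id"
        anchor = table["tss"] if i < 3 else (table["start"] + table["end"]) / 2
        cand = table[(table["chrom"] == chrom) & (np.abs(anchor - pos) <= 9e5)]
        cand = cand[~cand[col].isin(used)]
        target = cand.iloc[(np.abs((cand["tss"] if i < 3 else (cand["start"] + cand["end"]) / 2) - pos)).argmin()]
        qtls.append(PlantedQtl(snv_id, target[col], allele_fold=1.6))
        used.add(target[col])
    config.effects = effects
    config.links = links
    config.qtls = qtls
    return config


def default_endotype_config(seed: int = 0, n_pairs: int = 20) -> SimConfig:
    """Endotype-design conditions: half of the Monocyte-T1 gene effects
    are restricted to the GADA-first case subgroup."""
    return default_recovery_config(seed=seed, n_pairs=n_pairs, gada_specific=True)
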