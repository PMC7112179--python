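"""Seeded generators emulating the study's data-generating conditions.

Every stage of the pipeline can be exercised without any download: the
generators produce a toy genome annotation (non-overlapping genes and
TEs, a configurable fraction of TEs within 2 kb of a gene), negative-
binomial count matrices for four tissues x four replicates with planted
male-lineage TE activation and an optional rank-dependent coupling
between gene expression and neighboring TE activation, multi-mapped
read placements, beta-binomially overdispersed per-ear seed-marker
counts (intra-ear correlation calibrated so the Pearson dispersion is
about 1.8 at realistic ear sizes, with four ears per allele and
380-1,305 seeds per ear giving per-allele totals of roughly 1,500-5,200
seeds, mean about 2,800), and multinomial fertilization-outcome and
seed-census tables.

Every generator is a pure function of (config, seed); truth tables
accompany each synthetic dataset so recovery tests never re-derive the
planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotation import (
    GeneAnnotation,
    GenomeAnnotation,
    GenomicInterval,
    TEAnnotation,
    classify_proximity,
    superfamily_of,
)
from .gene_expression import ExpressionMatrix
from .seed_phenotype import OUTCOME_COLUMNS, EarSeedCensus, FertilizationTable
from .te_expression import CountMatrix, ReadPlacement
from .transmission import AlleleDataset, EarObservation

__all__ = [
    "SimulationConfig",
    "gen_annotation",
    "gen_counts",
    "gen_placements",
    "gen_ear_counts",
    "gen_phenotypes",
    "expression_from_counts",
]

_DEFAULT_FAMILY_MIX = {
    "RLG": 0.25,
    "RLC": 0.15,
    "LTR_unknown": 0.20,
    "DTM": 0.15,
    "DTA": 0.10,
    "LINE_L1": 0.10,
    "SINE": 0.05,
}

_DEFAULT_TISSUES = [
    ("seedling", 4),
    ("microspore", 4),
    ("mature_pollen", 4),
    ("sperm_cell", 4),
]

# male-lineage activation: (fraction of distal TEs activated, log2 effect)
_DEFAULT_ACTIVATION = {
    "microspore": (0.10, 2.0),
    "mature_pollen": (0.10, 2.0),
    "sperm_cell": (0.08, 2.0),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    n_tes: int = 800
    n_chroms: int = 4
    chrom_length: int = 12_000_000
    te_family_mix: dict = field(default_factory=lambda: dict(_DEFAULT_FAMILY_MIX))
    tissue_design: list = field(default_factory=lambda: list(_DEFAULT_TISSUES))
    # negative-binomial count model (natural-log mean scale)
    nb_mean_log_mu: float = 3.0
    nb_log_sd: float = 1.2
    nb_dispersion: float = 0.1
    te_activation: dict = field(default_factory=lambda: dict(_DEFAULT_ACTIVATION))
    te_down_fraction: float = 0.05
    # coupling between a gene's expression rank and the activation
    # probability of its <2 kb TEs in the coupled tissues (0 = none)
    coupling_kappa: float = 0.0
    coupled_tissues: tuple = ("mature_pollen", "sperm_cell")
    proximity_fraction: float = 0.3
    gene_class_fraction: float = 0.15  # planted per class
    gene_class_log2_boost: float = 4.0
    # read placements
    n_reads: int = 400
    multiplicity_probs: dict = field(
        default_factory=lambda: {1: 0.81, 2: 0.09, 4: 0.06, 10: 0.04}
    )
    # transmission experiment (study scale: 56 alleles, ~2,807 seeds each)
    class_design: dict = field(
        default_factory=lambda: {"seedling": 10, "sperm_cell": 11, "vegetative_cell": 35}
    )
    ears_per_allele: int = 4
    plants_per_allele: int = 2
    seeds_per_ear_range: tuple = (380, 1305)
    true_rates: Optional[dict] = None  # allele_id -> true male transmission rate
    overdispersion_rho: float = 0.00095  # phi ~ 1 + (nbar-1) rho ~ 1.8
    # phenotype experiment
    outcome_probs: dict = field(
        default_factory=lambda: {
            "wild_type": [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            "mutant": [0.5, 1 / 6, 1 / 6, 0.0, 0.0, 1 / 6],
        }
    )
    ovules_per_group: dict = field(default_factory=lambda: {"wild_type": 28, "mutant": 12})
    census_design: dict = field(
        default_factory=lambda: {
            "control_1": (6, 0.02),
            "control_2": (6, 0.02),
            "mutant_het": (6, 0.05),
            "mutant_hom": (6, 0.10),
        }
    )
    census_seeds_per_ear: int = 300


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def gen_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes and TEs; a configured fraction of TEs
    lands within 2 kb of a gene, the rest far from every gene."""
    rng = np.random.default_rng(config.seed)
    fams = list(config.te_family_mix)
    fam_p = np.array([config.te_family_mix[f] for f in fams], dtype=float)
    fam_p = fam_p / fam_p.sum()

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genes_per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    tes_per_chrom = np.array_split(np.arange(config.n_tes), config.n_chroms)

    # per chromosome, lay out alternating slots on a fixed grid so that
    # features never overlap and "distal" slots are >2 kb from any gene
    slot = 24_000  # grid pitch; leaves >= 8 kb between neighboring features
    genes: list = []
    tes: list = []
    centromeres = {}
    for ci, chrom in enumerate(chroms):
        gene_idx = genes_per_chrom[ci]
        te_idx = tes_per_chrom[ci]
        n_slots = len(gene_idx) + len(te_idx)
        if (n_slots + 2) * slot > config.chrom_length:
            raise ValueError("features cannot fit in chrom_length")
        positions = (np.arange(n_slots) + 1) * slot
        # interleave genes and TEs deterministically on the grid
        order = rng.permutation(n_slots)
        gene_slots = np.sort(order[: len(gene_idx)])
        te_slots = np.sort(order[len(gene_idx) :])
        gene_spans = []  # (start, end) per gene, for near-TE hosts
        for gi, pos in zip(gene_idx, positions[gene_slots]):
            length = int(rng.integers(2000, 6000))
            n_exons = int(rng.integers(1, 4))
            start = int(pos)
            end = start + length - 1
            bounds = np.sort(rng.choice(np.arange(start + 1, end), 2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], dtype=int)
            edges = np.concatenate([[start], bounds, [end]])
            exons = tuple(
                GenomicInterval(chrom, int(edges[2 * k]), int(edges[2 * k + 1]), "+")
                for k in range(n_exons)
            )
            gid = f"gene{gi:05d}"
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    interval=GenomicInterval(chrom, start, end, "+"),
                    isoforms=((f"{gid}.t1", exons),),
                )
            )
            gene_spans.append((start, end))
        # near TEs sit just downstream of a host gene (gap < 2 kb); each
        # host is used once so features never overlap. Distal TEs sit
        # mid-gap on their own slot, >= 2 kb from every gene.
        host_pool = list(rng.permutation(len(gene_spans))) if gene_spans else []
        for ti, pos in zip(te_idx, positions[te_slots]):
            length = int(rng.integers(500, 8000))
            near = rng.random() < config.proximity_fraction and host_pool
            if near:
                _, host_end = gene_spans[host_pool.pop()]
                start = int(host_end + 1 + rng.integers(0, 2000))  # gap in [0, 1999]
            else:
                start = int(pos + 11_000)
            fam = fams[rng.choice(len(fams), p=fam_p)]
            tes.append(
                TEAnnotation(
                    te_id=f"te{ti:05d}",
                    interval=GenomicInterval(chrom, start, start + length - 1, "."),
                    family=fam,
                    superfamily_class=superfamily_of(fam),
                )
            )
        mid = config.chrom_length // 2
        centromeres[chrom] = GenomicInterval(chrom, mid, mid + 100_000)
    return GenomeAnnotation(
        genes=genes,
        tes=tes,
        centromeres=centromeres,
        chrom_lengths={c: config.chrom_length for c in chroms},
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + dispersion * mu^2 via gamma-Poisson."""
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def gen_counts(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[CountMatrix, CountMatrix, dict]:
    """Gene and TE count matrices plus truth tables.

    TEs designated "activated" in a male tissue have their NB mean
    multiplied by 2**log2_effect there; with ``coupling_kappa > 0`` the
    activation probability of a near-gene TE in the coupled tissues
    scales with its neighbor gene's expression quantile q in that tissue
    as ``f0 * (1 + kappa * (2q - 1))`` (clipped to [0, 1]), so kappa = 0
    recovers uniform activation. A small fraction of distal+near TEs is
    planted down-regulated with the mirrored rule. Truth tables list the
    planted gene classes and the activated/deactivated TE ids per tissue.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = [g.gene_id for g in annotation.genes]
    te_ids = [t.te_id for t in annotation.tes]
    tissues = [t for t, _ in config.tissue_design]

    # planted gene classes: boost in the class tissue
    cls_of_tissue = {"seedling": "seedling", "mature_pollen": "vegetative_cell", "sperm_cell": "sperm_cell"}
    classes = ["seedling", "vegetative_cell", "sperm_cell"]
    n_cls = int(config.gene_class_fraction * len(gene_ids))
    perm = rng.permutation(len(gene_ids))
    planted_class = {gid: "none" for gid in gene_ids}
    for k, cls in enumerate(classes):
        for idx in perm[k * n_cls : (k + 1) * n_cls]:
            planted_class[gene_ids[idx]] = cls

    base_gene = rng.normal(config.nb_mean_log_mu, config.nb_log_sd, len(gene_ids))
    base_te = rng.normal(config.nb_mean_log_mu - 1.0, config.nb_log_sd, len(te_ids))

    gene_mean = {}  # tissue -> vector of NB means
    boost = config.gene_class_log2_boost * np.log(2.0)
    for tissue in tissues:
        mu = base_gene.copy()
        cls = cls_of_tissue.get(tissue)
        if cls is not None:
            mask = np.array([planted_class[g] == cls for g in gene_ids])
            mu = mu + boost * mask
        gene_mean[tissue] = np.exp(mu)

    # neighbor gene of each TE (nearest within 2 kb), for coupling
    _, gene_to_tes = classify_proximity(annotation, 2000)
    te_neighbor = {}
    for gid, tlist in gene_to_tes.items():
        for tid in tlist:
            te_neighbor.setdefault(tid, gid)

    activated: dict = {t: set() for t in tissues}
    deactivated: dict = {t: set() for t in tissues}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for tissue, (frac, _eff) in config.te_activation.items():
        if tissue not in tissues:
            continue
        q = None
        if config.coupling_kappa > 0 and tissue in config.coupled_tissues:
            ranks = np.argsort(np.argsort(gene_mean[tissue]))
            q = ranks / max(len(gene_ids) - 1, 1)
        for j, tid in enumerate(te_ids):
            f_up = frac
            f_down = config.te_down_fraction
            if q is not None and tid in te_neighbor:
                gq = q[gene_index[te_neighbor[tid]]]
                f_up = float(np.clip(frac * (1.0 + config.coupling_kappa * (2.0 * gq - 1.0)), 0.0, 1.0))
                f_down = float(np.clip(config.te_down_fraction * (1.0 - config.coupling_kappa * (2.0 * gq - 1.0)), 0.0, 1.0))
            u = rng.random()
            if u < f_up:
                activated[tissue].add(tid)
            elif u < f_up + f_down:
                deactivated[tissue].add(tid)

    te_mean = {}
    for tissue in tissues:
        mu = base_te.copy()
        if tissue in config.te_activation:
            eff = config.te_activation[tissue][1] * np.log(2.0)
            up = np.array([t in activated[tissue] for t in te_ids])
            down = np.array([t in deactivated[tissue] for t in te_ids])
            mu = mu + eff * up - eff * down
        te_mean[tissue] = np.exp(mu)

    samples = []
    gene_cols = []
    te_cols = []
    for tissue, n_rep in config.tissue_design:
        for r in range(1, n_rep + 1):
            gcol = _nb_draw(rng, gene_mean[tissue], config.nb_dispersion)
            tcol = _nb_draw(rng, te_mean[tissue], config.nb_dispersion)
            lib = int(gcol.sum() + tcol.sum())
            samples.append((f"{tissue}_{r}", tissue, r, lib))
            gene_cols.append(gcol)
            te_cols.append(tcol)

    gene_counts = CountMatrix(gene_ids, samples, np.column_stack(gene_cols).astype(float))
    te_counts = CountMatrix(te_ids, list(samples), np.column_stack(te_cols).astype(float))
    truth = {
        "planted_class": planted_class,
        "activated": activated,
        "deactivated": deactivated,
        "te_neighbor_gene": te_neighbor,
    }
    return gene_counts, te_counts, truth


def expression_from_counts(
    gene_counts: CountMatrix, annotation: GenomeAnnotation
) -> ExpressionMatrix:
    """FPKM matrix from gene counts using annotated transcript lengths
    and per-sample assigned totals as the mapped-fragment denominator."""
    lengths = np.array(
        [annotation.gene_by_id[g].transcript_length() for g in gene_counts.feature_ids],
        dtype=float,
    )
    totals = gene_counts.values.sum(axis=0)
    fpkm = gene_counts.values / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
    return ExpressionMatrix(
        feature_ids=list(gene_counts.feature_ids),
        samples=[(s[0], s[1], s[2]) for s in gene_counts.samples],
        fpkm_values=fpkm,
    )


# ---------------------------------------------------------------------------
# read placements
# ---------------------------------------------------------------------------

def gen_placements(config: SimulationConfig, annotation: GenomeAnnotation) -> list:
    """Reads with a configured multiplicity mix; loci inside TEs or background."""
    rng = np.random.default_rng(config.seed + 2)
    mults = np.array(list(config.multiplicity_probs), dtype=int)
    probs = np.array([config.multiplicity_probs[int(m)] for m in mults], dtype=float)
    probs = probs / probs.sum()
    chroms = sorted(annotation.chrom_lengths)
    placements = []
    for i in range(config.n_reads):
        k = int(mults[rng.choice(len(mults), p=probs)])
        loci = []
        for _ in range(k):
            if annotation.tes and rng.random() < 0.8:
                te = annotation.tes[rng.integers(len(annotation.tes))]
                span = max(te.interval.length - 100, 1)
                start = te.interval.start + int(rng.integers(0, span))
                loci.append(GenomicInterval(te.interval.chrom, start, min(start + 99, te.interval.end)))
            else:
                chrom = chroms[rng.integers(len(chroms))]
                start = int(rng.integers(1, annotation.chrom_lengths[chrom] - 100))
                loci.append(GenomicInterval(chrom, start, start + 99))
        placements.append(ReadPlacement(read_id=f"read{i:06d}", candidate_loci=tuple(loci)))
    return placements


# ---------------------------------------------------------------------------
# ear counts
# ---------------------------------------------------------------------------

def _beta_binomial(
    rng: np.random.Generator, n: int, mean: float, rho: float
) -> int:
    if rho < 0 or rho >= 1:
        raise ValueError("overdispersion rho must lie in [0, 1)")
    if rho == 0:
        return int(rng.binomial(n, mean))
    conc = (1.0 - rho) / rho
    p = rng.beta(mean * conc, (1.0 - mean) * conc)
    return int(rng.binomial(n, p))


def gen_ear_counts(config: SimulationConfig) -> list:
    """Beta-binomial per-ear seed-marker counts for every allele.

    Defaults mirror the study design: 56 alleles split 10 seedling / 11
    sperm cell / 35 vegetative cell, four male ears (and four female
    control ears) per allele from two plants, 380-1,305 seeds per ear,
    all true rates 0.5 unless ``true_rates`` plants something else.
    """
    rng = np.random.default_rng(config.seed + 3)
    lo, hi = config.seeds_per_ear_range

    alleles = []
    for cls, n in config.class_design.items():
        for k in range(n):
            alleles.append((f"{cls[:2]}_allele{k:03d}", cls))
    true_rates = dict(config.true_rates or {})

    out = []
    for i, (aid, cls) in enumerate(alleles):
        rate = float(true_rates.get(aid, 0.5))
        log2_fpkm = float(rng.uniform(5.0, 11.0))
        ears = []
        for direction in ("male", "female"):
            d_rate = rate if direction == "male" else 0.5
            for e in range(config.ears_per_allele):
                plant = f"{aid}_p{e % config.plants_per_allele + 1}"
                n_total = int(rng.integers(lo, hi + 1))
                n_marked = _beta_binomial(rng, n_total, d_rate, config.overdispersion_rho)
                ears.append(
                    EarObservation(
                        allele_id=aid,
                        plant_id=plant,
                        ear_id=f"{aid}_{direction}_e{e + 1}",
                        direction=direction,
                        marker="GFP",
                        n_marked=n_marked,
                        n_total=n_total,
                    )
                )
        out.append(AlleleDataset(aid, f"gene_{aid}", cls, log2_fpkm, ears))
    return out


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def gen_phenotypes(config: SimulationConfig) -> tuple[FertilizationTable, list]:
    """Multinomial ovule outcomes per pollen parent plus per-ear seed censuses."""
    rng = np.random.default_rng(config.seed + 4)
    groups = {}
    for g, probs in config.outcome_probs.items():
        p = np.asarray(probs, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"outcome probabilities for {g!r} must sum to 1")
        draw = rng.multinomial(config.ovules_per_group[g], p)
        groups[g] = dict(zip(OUTCOME_COLUMNS, (int(x) for x in draw)))
    table = FertilizationTable(groups=groups)

    censuses = []
    for g, (n_ears, small_rate) in config.census_design.items():
        for e in range(n_ears):
            n = config.census_seeds_per_ear
            n_small = int(rng.binomial(n, small_rate))
            censuses.append(
                EarSeedCensus(
                    ear_id=f"{g}_e{e + 1}",
                    genotype_group=g,
                    n_small=n_small,
                    n_normal=n - n_small,
                    seedless_area_pct=float(100.0 * rng.beta(2, 50) + (5.0 if "hom" in g else 0.0)),
                )
            )
    return table, censuses
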