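"""Genome annotation model and interval arithmetic.

Genes and transposable elements are carried as 1-based inclusive
intervals (the GFF3 convention). The central operation is the 2 kb
proximity partition: a TE lying with a gap of less than ``threshold_bp``
bases from any gene body (edge to edge, strand-agnostic) is ``near_gene``
and excluded from element-level expression analysis, because transcripts
overlapping or abutting genes cannot be distinguished from genic
read-through; everything else is ``distal``. A TE with a gap of exactly
the threshold counts as distal ("more than 2 kb away" defines the
analysis set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import gffutils
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TEAnnotation",
    "GeneAnnotation",
    "GenomeAnnotation",
    "gap_distance",
    "classify_proximity",
    "distance_to_centromere",
    "read_gff3",
    "write_gff3",
    "write_bed6",
    "read_centromere_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class TEAnnotation:
    te_id: str
    interval: GenomicInterval
    family: str = "unknown"
    superfamily_class: str = "other"  # LTR / DNA / LINE / SINE / other

    @property
    def length_bp(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    interval: GenomicInterval
    # list of (isoform_id, exon intervals); transcript length = sum of exon lengths
    isoforms: tuple = ()

    def transcript_length(self, isoform_id: Optional[str] = None) -> int:
        """Summed exon length of one isoform (default: longest)."""
        if not self.isoforms:
            return self.interval.length
        lengths = {iid: sum(e.length for e in exons) for iid, exons in self.isoforms}
        if isoform_id is None:
            return max(lengths.values())
        return lengths[isoform_id]


@dataclass
class GenomeAnnotation:
    genes: list = field(default_factory=list)
    tes: list = field(default_factory=list)
    centromeres: dict = field(default_factory=dict)  # chrom -> GenomicInterval
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes] + [t.te_id for t in self.tes]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids must be unique")
        for feat in list(self.genes) + list(self.tes):
            iv = feat.interval
            if iv.chrom in self.chrom_lengths and iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(f"feature exceeds chromosome length: {feat}")

    @property
    def te_by_id(self) -> dict:
        return {t.te_id: t for t in self.tes}

    @property
    def gene_by_id(self) -> dict:
        return {g.gene_id: g for g in self.genes}


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Bases strictly between two intervals; 0 on overlap/abutment; None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.end >= b.start and b.end >= a.start:
        return 0
    if a.end < b.start:
        return b.start - a.end - 1
    return a.start - b.end - 1


def classify_proximity(
    annotation: GenomeAnnotation, threshold_bp: int = 2000
) -> tuple[dict, dict]:
    """Partition TEs into near_gene / distal and invert the relation.

    Returns ``(te_category, gene_to_tes)`` where a TE is ``near_gene``
    iff its gap to at least one gene body is strictly below
    ``threshold_bp`` (overlap counts as near), and ``gene_to_tes`` maps
    each gene id to the sorted list of TE ids within the threshold.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be positive")
    if not annotation.genes:
        warnings.warn("no genes in annotation: all TEs classified distal", stacklevel=2)

    genes_by_chrom: dict = {}
    for g in annotation.genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)

    te_category: dict = {}
    gene_to_tes: dict = {g.gene_id: [] for g in annotation.genes}
    for te in annotation.tes:
        near = False
        for g in genes_by_chrom.get(te.interval.chrom, ()):
            d = gap_distance(te.interval, g.interval)
            if d is not None and d < threshold_bp:
                near = True
                gene_to_tes[g.gene_id].append(te.te_id)
        te_category[te.te_id] = "near_gene" if near else "distal"
    for v in gene_to_tes.values():
        v.sort()
    return te_category, gene_to_tes


def distance_to_centromere(te: TEAnnotation, annotation: GenomeAnnotation) -> int:
    """Gap from a TE to its chromosome's annotated centromere (0 if within)."""
    chrom = te.interval.chrom
    if chrom not in annotation.centromeres:
        raise KeyError(f"no centromere annotated for chromosome {chrom}")
    d = gap_distance(te.interval, annotation.centromeres[chrom])
    assert d is not None
    return d


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_SUPERFAMILY_PREFIX = {
    "RL": "LTR",  # RLG/RLC/RLX Gypsy, Copia, unknown LTR
    "DT": "DNA",  # DTM Mutator, DTA hAT, ...
    "DH": "DNA",
    "LI": "LINE",
    "SI": "SINE",
    "RI": "LINE",
    "RS": "SINE",
}


def superfamily_of(family: str) -> str:
    """Map a TE family code (e.g. RLG, DTM, LINE-L1, SINE) to a superfamily class."""
    fam = family.upper()
    if fam.startswith("LTR") or fam.startswith("RL"):
        return "LTR"
    if fam.startswith("LINE") or fam.startswith("RI") or fam.startswith("LI"):
        return "LINE"
    if fam.startswith("SINE") or fam.startswith("RS"):
        return "SINE"
    if fam.startswith("DT") or fam.startswith("DNA") or fam.startswith("DH"):
        return "DNA"
    return _SUPERFAMILY_PREFIX.get(fam[:2], "other")


def read_gff3(
    gene_path: Optional[str] = None,
    te_path: Optional[str] = None,
    centromere_path: Optional[str] = None,
    family_attribute: str = "family",
) -> GenomeAnnotation:
    """Load genes (gene/mRNA/exon features) and TEs from GFF3 files.

    TE family is read from the ``family_attribute`` GFF3 attribute,
    falling back to ``Classification``. Centromeres come from a TSV
    (chrom, start, end).
    """
    genes: list = []
    tes: list = []
    chrom_lengths: dict = {}

    if gene_path is not None:
        db = gffutils.create_db(
            str(gene_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for g in db.features_of_type("gene"):
            isoforms = []
            for mrna in db.children(g, featuretype="mRNA"):
                exons = tuple(
                    GenomicInterval(e.seqid, e.start, e.end, e.strand or ".")
                    for e in db.children(mrna, featuretype="exon")
                )
                isoforms.append((mrna.id, exons))
            genes.append(
                GeneAnnotation(
                    gene_id=g.id,
                    interval=GenomicInterval(g.seqid, g.start, g.end, g.strand or "."),
                    isoforms=tuple(isoforms),
                )
            )
    if te_path is not None:
        db = gffutils.create_db(
            str(te_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for t in db.all_features():
            fam = t.attributes.get(family_attribute, t.attributes.get("Classification", ["unknown"]))[0]
            tes.append(
                TEAnnotation(
                    te_id=t.id,
                    interval=GenomicInterval(t.seqid, t.start, t.end, t.strand or "."),
                    family=fam,
                    superfamily_class=superfamily_of(fam),
                )
            )
    centromeres = read_centromere_table(centromere_path) if centromere_path else {}
    for feat in genes:
        chrom_lengths.setdefault(feat.interval.chrom, 0)
        chrom_lengths[feat.interval.chrom] = max(chrom_lengths[feat.interval.chrom], feat.interval.end)
    for feat in tes:
        chrom_lengths.setdefault(feat.interval.chrom, 0)
        chrom_lengths[feat.interval.chrom] = max(chrom_lengths[feat.interval.chrom], feat.interval.end)
    return GenomeAnnotation(genes=genes, tes=tes, centromeres=centromeres, chrom_lengths=chrom_lengths)


def read_centromere_table(path: str) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["chrom"]): GenomicInterval(str(r["chrom"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    }


def write_gff3(annotation: GenomeAnnotation, gene_path: str, te_path: str) -> None:
    """Write genes (gene/mRNA/exon) and TEs as two GFF3 files."""
    with open(gene_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda x: (x.interval.chrom, x.interval.start, x.gene_id)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tpollentx\tgene\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for iid, exons in g.isoforms:
                fh.write(
                    f"{iv.chrom}\tpollentx\tmRNA\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f"ID={iid};Parent={g.gene_id}\n"
                )
                for j, e in enumerate(exons, 1):
                    fh.write(
                        f"{e.chrom}\tpollentx\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t"
                        f"ID={iid}.exon{j};Parent={iid}\n"
                    )
    with open(te_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(annotation.tes, key=lambda x: (x.interval.chrom, x.interval.start, x.te_id)):
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tpollentx\ttransposable_element\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={t.te_id};family={t.family}\n"
            )


def write_bed6(features: list, path: str, name_of=lambda f: f.te_id, score: int = 0) -> None:
    """BED6 export (0-based half-open) of a feature list."""
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name_of(f)}\t{score}\t{iv.strand}\n")
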