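"""Gene-level abundance (FPKM) and expression-class assignment.

Highly expressed genes are operationally defined as the top 20% of a
tissue by FPKM and grouped into three mutually exclusive classes for the
transmission study: *vegetative cell* (top 20% in mature pollen with
FPKM(MP) > FPKM(SC)), *sperm cell* (top 20% in sperm cells with
FPKM(SC) > FPKM(MP)), and *seedling* (top 20% in seedling, excluding any
gene highly expressed in either MP or SC). A very-high flag marks the
log2(FPKM) > 8 subset, roughly the top 5% within a class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneClassAssignment",
    "fpkm",
    "assign_classes",
    "top_set_overlap_summary",
]


@dataclass
class ExpressionMatrix:
    """Feature-by-sample FPKM matrix with per-tissue replicate means."""

    feature_ids: list
    samples: list  # of (sample_id, tissue, replicate)
    fpkm_values: np.ndarray

    def __post_init__(self) -> None:
        self.fpkm_values = np.asarray(self.fpkm_values, dtype=float)
        if self.fpkm_values.shape != (len(self.feature_ids), len(self.samples)):
            raise ValueError("FPKM matrix dimensions inconsistent with labels")
        if np.any(self.fpkm_values < 0):
            raise ValueError("FPKM must be non-negative")

    def tissue_means(self) -> pd.DataFrame:
        tissues = [s[1] for s in self.samples]
        out = {}
        for tissue in dict.fromkeys(tissues):
            cols = [j for j, t in enumerate(tissues) if t == tissue]
            out[tissue] = self.fpkm_values[:, cols].mean(axis=1)
        return pd.DataFrame(out, index=self.feature_ids)


@dataclass
class GeneClassAssignment:
    gene_id: str
    gene_class: str  # seedling / vegetative_cell / sperm_cell / unclassified
    fpkm_mp: float
    fpkm_sc: float
    fpkm_seedling: float
    very_high: bool = False


def fpkm(fragments: float, transcript_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if fragments < 0:
        raise ValueError("fragment count must be non-negative")
    if transcript_length_bp <= 0 or total_mapped_fragments <= 0:
        raise ValueError("transcript length and total mapped fragments must be positive")
    return fragments / ((transcript_length_bp / 1e3) * (total_mapped_fragments / 1e6))


def _top_quantile_ids(means: pd.Series, quantile: float, expressed_only: bool) -> set:
    s = means[means > 0] if expressed_only else means
    if s.empty:
        return set()
    n_top = int(np.ceil(quantile * len(s)))
    # stable order: descending expression, ties broken by feature id
    order = s.sort_index().sort_values(ascending=False, kind="stable")
    return set(order.index[:n_top])


def assign_classes(
    expr: ExpressionMatrix,
    quantile: float = 0.20,
    high_threshold_log2: float = 8.0,
    mp_tissue: str = "mature_pollen",
    sc_tissue: str = "sperm_cell",
    seedling_tissue: str = "seedling",
    expressed_only: bool = True,
) -> list:
    """Mutually exclusive seedling / vegetative-cell / sperm-cell classes.

    The top-``quantile`` membership is computed per tissue on tissue-mean
    FPKM (over expressed features by default). Genes in the top set of
    both MP and SC are split by which FPKM is larger; an exact tie leaves
    the gene unclassified with a warning.
    """
    means = expr.tissue_means()
    for t in (mp_tissue, sc_tissue, seedling_tissue):
        if t not in means.columns:
            raise KeyError(f"tissue {t!r} missing from expression matrix")
    top_mp = _top_quantile_ids(means[mp_tissue], quantile, expressed_only)
    top_sc = _top_quantile_ids(means[sc_tissue], quantile, expressed_only)
    top_se = _top_quantile_ids(means[seedling_tissue], quantile, expressed_only)

    out = []
    for gid in expr.feature_ids:
        f_mp = float(means.at[gid, mp_tissue])
        f_sc = float(means.at[gid, sc_tissue])
        f_se = float(means.at[gid, seedling_tissue])
        cls = "unclassified"
        if gid in top_mp and f_mp > f_sc:
            cls = "vegetative_cell"
        elif gid in top_sc and f_sc > f_mp:
            cls = "sperm_cell"
        elif gid in top_se and gid not in top_mp and gid not in top_sc:
            cls = "seedling"
        elif gid in top_mp and gid in top_sc and f_mp == f_sc:
            warnings.warn(f"gene {gid} tied between MP and SC FPKM; unclassified", stacklevel=2)
        class_fpkm = {"vegetative_cell": f_mp, "sperm_cell": f_sc, "seedling": f_se}.get(cls, 0.0)
        very_high = cls != "unclassified" and class_fpkm > 0 and np.log2(class_fpkm) > high_threshold_log2
        out.append(GeneClassAssignment(gid, cls, f_mp, f_sc, f_se, very_high))
    return out


def top_set_overlap_summary(
    expr: ExpressionMatrix, tissues: Sequence[str], top_n: int
) -> dict:
    """Histogram of top-ranked features by the number of tissues sharing them.

    Returns per-tissue and global multiplicity histograms: for each
    tissue's top-``top_n`` set, how many of its members are top-ranked in
    exactly 1, 2, ... |tissues| tissues. Ties at the boundary break by
    feature id (descending expression, then lexicographic id).
    """
    if top_n > len(expr.feature_ids):
        raise ValueError("top_n exceeds feature count")
    means = expr.tissue_means()
    top_sets = {}
    for t in tissues:
        order = means[t].sort_index().sort_values(ascending=False, kind="stable")
        top_sets[t] = set(order.index[:top_n])
    multiplicity = {}
    for fid in set().union(*top_sets.values()):
        multiplicity[fid] = sum(fid in s for s in top_sets.values())
    k = len(tissues)
    per_tissue = {
        t: {m: sum(multiplicity[f] == m for f in s) for m in range(1, k + 1)}
        for t, s in top_sets.items()
    }
    global_hist = {m: sum(v == m for v in multiplicity.values()) for m in range(1, k + 1)}
    return {"per_tissue": per_tissue, "global": global_hist, "top_sets": top_sets}
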