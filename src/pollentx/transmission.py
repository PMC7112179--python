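"""Marker-transmission fitness analysis.

A heterozygous insertion outcrossed through the male should transmit its
seed marker (GFP or the linked C1 anthocyanin transgene) to 50% of
progeny under Mendelian expectation; a deficit measures the fitness cost
of the mutation to the haploid gametophyte. Per-ear marked/total seed
counts are overdispersed relative to binomial sampling (ears differ in
maternal environment), so each allele is tested with the quasi-binomial
framework of :mod:`pollentx.stats`, with the Pearson dispersion pooled
across the alleles of an expression class by default and BH correction
applied within class x cross-direction.

QC mirrors the field protocol: ears consistent with a second unlinked
insertion (~75% marker transmission) are excluded, and an allele needs
at least three male outcross ears from at least two plants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .stats import (
    ContingencyTable2x2,
    TestResult,
    auxiliary_test,
    benjamini_hochberg,
    binomial_deviance,
    fisher_exact_2x2,
    linear_regression,
    pearson_dispersion,
    quasibinomial_test,
    RegressionResult,
)

__all__ = [
    "EarObservation",
    "AlleleDataset",
    "AlleleTransmission",
    "qc_ears",
    "test_all_alleles",
    "class_defect_comparison",
    "expression_fitness_regression",
    "read_ear_table",
    "write_ear_table",
    "results_frame",
]


@dataclass(frozen=True)
class EarObservation:
    allele_id: str
    plant_id: str
    ear_id: str
    direction: str  # male / female
    marker: str = "GFP"  # GFP or C1 (treated identically)
    n_marked: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_marked <= self.n_total) or self.n_total <= 0:
            raise ValueError(f"invalid ear counts for {self.allele_id}/{self.ear_id}")

    @property
    def rate(self) -> float:
        return self.n_marked / self.n_total


@dataclass
class AlleleDataset:
    allele_id: str
    gene_id: str
    expression_class: str  # seedling / vegetative_cell / sperm_cell
    log2_fpkm: float
    ears: list = field(default_factory=list)

    def ears_in(self, direction: str) -> list:
        return [e for e in self.ears if e.direction == direction]


@dataclass
class AlleleTransmission:
    allele_id: str
    gene_id: str
    expression_class: str
    log2_fpkm: float
    direction: str
    transmission_rate: float
    p_value: float
    p_adjusted: Optional[float]
    n_ears: int
    n_seeds: int
    dispersion_phi: float
    significant: bool = False


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_ears(
    dataset: AlleleDataset,
    min_male_ears: int = 3,
    min_plants: int = 2,
    double_insertion_rate: float = 0.70,
    double_insertion_p: float = 0.01,
) -> tuple[Optional[AlleleDataset], list]:
    """Exclude multi-insertion ears and under-sampled alleles.

    An ear is excluded as a putative double insertion when its marked
    fraction exceeds ``double_insertion_rate`` AND an exact binomial test
    rejects 0.5 upward at ``double_insertion_p`` (a rate threshold alone
    would discard large Mendelian ears on noise). The allele is dropped
    entirely when the male direction retains fewer than ``min_male_ears``
    ears or fewer than ``min_plants`` distinct plants. Returns the
    filtered dataset (or None if dropped) and a report of exclusions.
    """
    report = []
    kept = []
    for ear in dataset.ears:
        if ear.rate > double_insertion_rate:
            res = auxiliary_test("exact_binomial", k=ear.n_marked, n=ear.n_total, p0=0.5)
            # one-sided evidence of excess: halve the two-sided p when above null
            p_greater = res.p_value / 2.0
            if p_greater < double_insertion_p:
                report.append(
                    {
                        "allele_id": dataset.allele_id,
                        "ear_id": ear.ear_id,
                        "reason": "double_insertion",
                        "detail": f"rate={ear.rate:.3f}, p_greater={p_greater:.2e}",
                    }
                )
                continue
        kept.append(ear)

    male = [e for e in kept if e.direction == "male"]
    n_plants = len({e.plant_id for e in male})
    if len(male) < min_male_ears or n_plants < min_plants:
        report.append(
            {
                "allele_id": dataset.allele_id,
                "ear_id": None,
                "reason": "insufficient_male_replication",
                "detail": f"{len(male)} male ears from {n_plants} plants",
            }
        )
        return None, report
    return replace(dataset, ears=kept), report


# ---------------------------------------------------------------------------
# per-allele testing
# ---------------------------------------------------------------------------

def _pooled_phi(datasets: list, direction: str) -> tuple[float, int]:
    """Pearson dispersion pooled across alleles: each allele contributes
    residuals around its own pooled rate; df = ears - alleles in scope."""
    chi2 = 0.0
    n_ears = 0
    n_alleles = 0
    for ds in datasets:
        ears = ds.ears_in(direction)
        if not ears:
            continue
        y = np.array([e.n_marked for e in ears], dtype=float)
        n = np.array([e.n_total for e in ears], dtype=float)
        rate = min(max(y.sum() / n.sum(), 1e-8), 1 - 1e-8)
        chi2 += np.sum((y - n * rate) ** 2 / (n * rate * (1 - rate)))
        n_ears += len(ears)
        n_alleles += 1
    df = n_ears - n_alleles
    if df <= 0:
        raise ValueError(
            "zero residual df for pooled dispersion; more ears per allele are required"
        )
    return max(chi2 / df, 1e-8), df


def test_all_alleles(
    datasets: list,
    direction: str = "male",
    phi_pooling: str = "per_class",
    alpha: float = 0.05,
    null_rate: float = 0.5,
) -> list:
    """Quasi-likelihood test of every allele against the Mendelian rate.

    ``phi_pooling='per_class'`` estimates one Pearson dispersion per
    expression class (df = ears - alleles in the class) and refers each
    allele's scaled deviance drop to F(1, df); ``'per_allele'`` estimates
    phi per allele on its own k-1 df. BH correction is applied within
    expression class x direction (``'global'`` pooling corrects across
    everything at once).
    """
    if phi_pooling not in ("per_class", "per_allele", "global"):
        raise ValueError(f"unknown phi_pooling {phi_pooling!r}")

    by_class: dict = {}
    for ds in datasets:
        by_class.setdefault(ds.expression_class, []).append(ds)

    scopes = (
        {"all": datasets}.items() if phi_pooling == "global" else by_class.items()
    )
    results: list = []
    for _scope_name, members in scopes:
        phi = df_phi = None
        if phi_pooling in ("per_class", "global"):
            phi, df_phi = _pooled_phi(members, direction)
        scope_results = []
        for ds in members:
            ears = ds.ears_in(direction)
            if not ears:
                continue
            y = [e.n_marked for e in ears]
            n = [e.n_total for e in ears]
            if phi_pooling == "per_allele":
                fit, res = quasibinomial_test(y, n, null_rate)
            else:
                fit, res = quasibinomial_test(y, n, null_rate, phi_override=phi, phi_df=df_phi)
            scope_results.append(
                AlleleTransmission(
                    allele_id=ds.allele_id,
                    gene_id=ds.gene_id,
                    expression_class=ds.expression_class,
                    log2_fpkm=ds.log2_fpkm,
                    direction=direction,
                    transmission_rate=fit.fitted_rate,
                    p_value=res.p_value,
                    p_adjusted=None,
                    n_ears=len(ears),
                    n_seeds=int(sum(n)),
                    dispersion_phi=fit.dispersion_phi,
                )
            )
        padj = benjamini_hochberg([r.p_value for r in scope_results])
        for r, pa in zip(scope_results, padj):
            r.p_adjusted = float(pa)
            r.significant = bool(pa < alpha)
        results.extend(scope_results)
    return results


# ---------------------------------------------------------------------------
# class-level comparisons and regressions
# ---------------------------------------------------------------------------

def _gene_defects(results: list) -> dict:
    """Gene-level defect flag: a gene is defective if any allele is significant."""
    flags: dict = {}
    for r in results:
        flags[r.gene_id] = flags.get(r.gene_id, False) or r.significant
    return flags


def class_defect_comparison(
    results: list,
    split_log2fpkm: float = 8.0,
    alternative: str = "two-sided",
) -> dict:
    """Fisher tests on gene-level defect proportions.

    Returns class-vs-class comparisons plus the high-vs-low expression
    split (at ``split_log2fpkm``) within the vegetative-cell class, each
    as ``(ContingencyTable2x2, TestResult)``.
    """
    by_class: dict = {}
    gene_class: dict = {}
    gene_fpkm: dict = {}
    for r in results:
        by_class.setdefault(r.expression_class, []).append(r)
        gene_class[r.gene_id] = r.expression_class
        gene_fpkm[r.gene_id] = max(gene_fpkm.get(r.gene_id, -np.inf), r.log2_fpkm)
    defects = _gene_defects(results)

    out: dict = {}
    classes = sorted(by_class)
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            genes_a = [g for g, c in gene_class.items() if c == ca]
            genes_b = [g for g, c in gene_class.items() if c == cb]
            if not genes_a or not genes_b:
                warnings.warn(f"empty class in comparison {ca} vs {cb}; skipped", stacklevel=2)
                continue
            da = sum(defects[g] for g in genes_a)
            db = sum(defects[g] for g in genes_b)
            table = ContingencyTable2x2(da, len(genes_a) - da, db, len(genes_b) - db)
            out[(ca, cb)] = (table, fisher_exact_2x2(table, alternative))

    vc_genes = [g for g, c in gene_class.items() if c == "vegetative_cell"]
    if vc_genes:
        high = [g for g in vc_genes if gene_fpkm[g] > split_log2fpkm]
        low = [g for g in vc_genes if gene_fpkm[g] <= split_log2fpkm]
        if high and low:
            dh = sum(defects[g] for g in high)
            dl = sum(defects[g] for g in low)
            table = ContingencyTable2x2(dh, len(high) - dh, dl, len(low) - dl)
            out[("vc_high", "vc_low")] = (table, fisher_exact_2x2(table, alternative))
    return out


def expression_fitness_regression(
    results: list, expression_class: str = "vegetative_cell"
) -> tuple[RegressionResult, RegressionResult]:
    """Two OLS fits within a class: rate ~ log2FPKM and -log10(p) ~ log2FPKM."""
    rows = [r for r in results if r.expression_class == expression_class]
    if len(rows) < 3:
        raise ValueError(f"need >= 3 alleles in class {expression_class!r}")
    x = [r.log2_fpkm for r in rows]
    rate = [r.transmission_rate for r in rows]
    neglogp = [-np.log10(max(r.p_value, 1e-300)) for r in rows]
    return linear_regression(x, rate), linear_regression(x, neglogp)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_EAR_COLUMNS = [
    "allele_id",
    "gene_id",
    "expression_class",
    "log2_fpkm",
    "plant_id",
    "ear_id",
    "direction",
    "marker",
    "n_marked",
    "n_total",
]


def write_ear_table(datasets: list, path: str) -> None:
    rows = []
    for ds in datasets:
        for e in ds.ears:
            rows.append(
                [ds.allele_id, ds.gene_id, ds.expression_class, ds.log2_fpkm,
                 e.plant_id, e.ear_id, e.direction, e.marker, e.n_marked, e.n_total]
            )
    pd.DataFrame(rows, columns=_EAR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ear_table(path: str) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (allele, gene, cls, fpkm), grp in df.groupby(
        ["allele_id", "gene_id", "expression_class", "log2_fpkm"], sort=True
    ):
        ears = [
            EarObservation(
                allele_id=str(allele),
                plant_id=str(r["plant_id"]),
                ear_id=str(r["ear_id"]),
                direction=str(r["direction"]),
                marker=str(r["marker"]),
                n_marked=int(r["n_marked"]),
                n_total=int(r["n_total"]),
            )
            for _, r in grp.iterrows()
        ]
        out.append(AlleleDataset(str(allele), str(gene), str(cls), float(fpkm), ears))
    return out


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "allele_id": r.allele_id,
                "gene_id": r.gene_id,
                "expression_class": r.expression_class,
                "log2_fpkm": r.log2_fpkm,
                "direction": r.direction,
                "transmission_rate": r.transmission_rate,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "n_ears": r.n_ears,
                "n_seeds": r.n_seeds,
                "dispersion_phi": r.dispersion_phi,
                "significant": r.significant,
            }
            for r in results
        ]
    )
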