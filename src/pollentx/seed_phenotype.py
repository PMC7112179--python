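"""Post-fertilization seed phenotype statistics.

Covers the three analyses downstream of the transmission screen:
per-ear small/aborted-seed fractions (or seedless-area percentages)
compared against control lines with Welch t-tests; classification of
4-days-after-pollination ovule outcomes into normal double fertilization
(one synergid penetrated, both embryo and endosperm developing) versus
everything else, compared between pollen parents by Fisher's exact
test; and the exact binomial test of mutant enrichment among genotyped
small seeds against the Mendelian 0.5 expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, TestResult, auxiliary_test, fisher_exact_2x2

__all__ = [
    "EarSeedCensus",
    "FertilizationTable",
    "census_tests",
    "fertilization_outcome_test",
    "small_seed_genotype_test",
    "read_census_table",
    "read_fertilization_table",
]

# ovule outcome columns, in the order of the published table layout:
# (one synergid penetrated, both synergids penetrated) x
# (both products, endosperm only, embryo only)
OUTCOME_COLUMNS = [
    "one_syn_both",
    "one_syn_endosperm_only",
    "one_syn_embryo_only",
    "both_syn_both",
    "both_syn_endosperm_only",
    "both_syn_embryo_only",
]


@dataclass
class EarSeedCensus:
    ear_id: str
    genotype_group: str
    n_small: int
    n_normal: int
    seedless_area_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_small < 0 or self.n_normal < 0 or self.n_small + self.n_normal == 0:
            raise ValueError(f"invalid seed counts for ear {self.ear_id}")

    @property
    def small_fraction(self) -> float:
        return self.n_small / (self.n_small + self.n_normal)


@dataclass
class FertilizationTable:
    """Per pollen-parent group: six ovule outcome counts (see OUTCOME_COLUMNS)."""

    groups: dict  # group label -> dict of OUTCOME_COLUMNS -> int

    def __post_init__(self) -> None:
        for g, row in self.groups.items():
            missing = [c for c in OUTCOME_COLUMNS if c not in row]
            if missing:
                raise ValueError(f"group {g!r} missing outcome counts {missing}")
            if any(row[c] < 0 for c in OUTCOME_COLUMNS):
                raise ValueError(f"negative outcome count in group {g!r}")

    def ovules(self, group: str) -> int:
        return sum(self.groups[group][c] for c in OUTCOME_COLUMNS)

    def classify(self, group: str) -> tuple[int, int]:
        """(normal, abnormal): normal = one synergid penetrated AND both
        embryo and endosperm developing; abnormal = everything else."""
        row = self.groups[group]
        normal = row["one_syn_both"]
        abnormal = self.ovules(group) - normal
        return normal, abnormal


def census_tests(
    censuses: Sequence[EarSeedCensus],
    treatment_groups: Sequence[str],
    control_groups: Sequence[str],
    measure: str = "small_fraction",
) -> dict:
    """Welch t-tests of each treatment group against each control group.

    ``measure`` is ``small_fraction`` (per-ear small/(small+normal)) or
    ``seedless_area_pct``. Returns {(treatment, control): TestResult}.
    """
    def values(group: str) -> np.ndarray:
        rows = [c for c in censuses if c.genotype_group == group]
        if len(rows) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 ears")
        if measure == "small_fraction":
            return np.array([c.small_fraction for c in rows])
        if measure == "seedless_area_pct":
            vals = [c.seedless_area_pct for c in rows]
            if any(v is None for v in vals):
                raise ValueError(f"group {group!r} has missing seedless area")
            return np.array(vals, dtype=float)
        raise ValueError(f"unknown measure {measure!r}")

    out = {}
    for t in treatment_groups:
        vt = values(t)
        for c in control_groups:
            out[(t, c)] = auxiliary_test("welch_t", a=vt, b=values(c))
    return out


def fertilization_outcome_test(
    table: FertilizationTable, group_a: str, group_b: str
) -> tuple[dict, TestResult]:
    """Normal/abnormal double-fertilization contingency between two pollen parents."""
    for g in (group_a, group_b):
        if g not in table.groups:
            raise KeyError(f"group {g!r} not in fertilization table")
        if table.ovules(g) == 0:
            raise ValueError(f"group {g!r} has zero ovules")
    na, aa = table.classify(group_a)
    nb, ab = table.classify(group_b)
    ct = ContingencyTable2x2(na, aa, nb, ab)
    classification = {
        group_a: {"normal": na, "abnormal": aa},
        group_b: {"normal": nb, "abnormal": ab},
    }
    return classification, fisher_exact_2x2(ct, "two-sided")


def small_seed_genotype_test(n_mutant: int, n_typed: int) -> TestResult:
    """Exact two-sided binomial test of mutant fraction among small seeds vs 0.5.

    0.5 is the Mendelian expectation conditional on sampling seeds,
    ignoring the overall transmission deficit (which would only make the
    observed enrichment more surprising).
    """
    if n_typed <= 0:
        raise ValueError("n_typed must be positive")
    if not 0 <= n_mutant <= n_typed:
        raise ValueError("need 0 <= n_mutant <= n_typed")
    res = auxiliary_test("exact_binomial", k=n_mutant, n=n_typed, p0=0.5)
    if res.estimate is not None and res.estimate > 0.5 and res.p_value < 0.05:
        res.flags.append("mutant_enriched")
    return res


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_census_table(path: str) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        area = r.get("seedless_area_pct")
        out.append(
            EarSeedCensus(
                ear_id=str(r["ear_id"]),
                genotype_group=str(r["genotype_group"]),
                n_small=int(r["n_small"]),
                n_normal=int(r["n_normal"]),
                seedless_area_pct=None if pd.isna(area) else float(area),
            )
        )
    return out


def read_fertilization_table(path: str) -> FertilizationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = {str(g): {c: int(df.at[g, c]) for c in OUTCOME_COLUMNS} for g in df.index}
    return FertilizationTable(groups=groups)
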