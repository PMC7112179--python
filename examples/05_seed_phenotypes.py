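"""Fertilization-outcome and seed-phenotype statistics.

Uses the published 4-days-after-pollination ovule counts: an ovule is a
normal double fertilization only if one synergid was penetrated and both
embryo and endosperm are developing; everything else (single
fertilization, both synergids penetrated) is abnormal.
"""

from pollentx import (
    FertilizationTable,
    fertilization_outcome_test,
    small_seed_genotype_test,
)
from pollentx.seed_phenotype import OUTCOME_COLUMNS

table = FertilizationTable(
    groups={
        "gex2_mutant": dict(zip(OUTCOME_COLUMNS, [6, 2, 2, 0, 0, 2])),
        "wild_type": dict(zip(OUTCOME_COLUMNS, [28, 0, 0, 0, 0, 0])),
    }
)
classification, res = fertilization_outcome_test(table, "gex2_mutant", "wild_type")
print("classification:", classification)
print(f"Fisher two-sided p = {res.p_value:.3g}")
# Half of the mutant-pollinated ovules are abnormal versus none of the
# wild-type ones, a strong double-fertilization defect.

geno = small_seed_genotype_test(19, 24)
print(f"\nsmall seeds carrying the mutation: {geno.estimate:.1%} (p = {geno.p_value:.4f})")
# Under Mendelian sampling small seeds would split 50/50; the observed
# enrichment ties the small-seed phenotype to the paternal mutation.
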