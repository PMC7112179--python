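"""End-to-end orchestration over a single artifact directory.

Each command reads its inputs from, and writes stable filenames into,
one output directory, so a full run is `simulate` -> `te-classify` ->
`diffexpr` -> `coexpress` -> `classify-genes` -> `transmission` ->
`phenotype` -> `report`. A manifest records the exact configuration,
seed and package version that produced the artifacts; re-running from
the manifest reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import read_gff3, write_gff3
from .coexpression import bin_and_count, bin_association
from .gene_expression import assign_classes
from .seed_phenotype import (
    OUTCOME_COLUMNS,
    census_tests,
    fertilization_outcome_test,
    read_census_table,
    read_fertilization_table,
)
from .simulate import (
    SimulationConfig,
    expression_from_counts,
    gen_annotation,
    gen_counts,
    gen_ear_counts,
    gen_phenotypes,
)
from .te_expression import (
    categorize_tes,
    nb_differential,
    read_counts_tsv,
    write_counts_tsv,
    write_de_tsv,
)
from .annotation import classify_proximity
from .transmission import (
    qc_ears,
    read_ear_table,
    results_frame,
    test_all_alleles,
    write_ear_table,
)

log = logging.getLogger("pollentx")

COMMANDS = (
    "simulate",
    "te-classify",
    "diffexpr",
    "coexpress",
    "classify-genes",
    "transmission",
    "phenotype",
    "report",
)


@dataclass
class PipelineConfig:
    """Analysis thresholds, all defaulting to the published constants."""

    seed: int = 0
    out_dir: str = "pollentx_out"
    proximity_bp: int = 2000
    min_total: int = 10
    alpha: float = 0.05
    top_quantile: float = 0.20
    n_top: int = 20000
    bin_size: int = 200
    high_log2fpkm: float = 8.0
    reference_tissue: str = "seedling"
    target_tissues: tuple = ("microspore", "mature_pollen", "sperm_cell")
    coexpression_tissues: tuple = ("mature_pollen", "sperm_cell")
    phi_pooling: str = "per_class"
    drop_samples: tuple = ()  # e.g. the aberrant sperm-cell replicate
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_tissues"] = list(self.target_tissues)
        d["coexpression_tissues"] = list(self.coexpression_tissues)
        d["drop_samples"] = list(self.drop_samples)
        return d


def _manifest(config: PipelineConfig, command: str, artifacts: list) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "command": command,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": sorted(artifacts),
    }


def _write_manifest(out: Path, manifest: dict) -> None:
    existing = []
    mpath = out / "manifest.json"
    if mpath.exists():
        existing = json.loads(mpath.read_text())
    existing.append(manifest)
    mpath.write_text(json.dumps(existing, indent=2))


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    return SimulationConfig(seed=config.seed, **config.simulation)


def run(command: str, config: PipelineConfig) -> dict:
    """Execute one pipeline command; returns the manifest entry written."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = {
        "simulate": _cmd_simulate,
        "te-classify": _cmd_te_classify,
        "diffexpr": _cmd_diffexpr,
        "coexpress": _cmd_coexpress,
        "classify-genes": _cmd_classify_genes,
        "transmission": _cmd_transmission,
        "phenotype": _cmd_phenotype,
        "report": _cmd_report,
    }[command]
    artifacts = handler(out, config)
    manifest = _manifest(config, command, artifacts)
    _write_manifest(out, manifest)
    log.info("%s: wrote %d artifacts to %s", command, len(artifacts), out)
    return manifest


def _require(out: Path, *names: str) -> None:
    for n in names:
        if not (out / n).exists():
            raise FileNotFoundError(f"missing input artifact: {out / n}")


def _cmd_simulate(out: Path, config: PipelineConfig) -> list:
    sim = _sim_config(config)
    ann = gen_annotation(sim)
    write_gff3(ann, out / "genes.gff3", out / "tes.gff3")
    cent = pd.DataFrame(
        [(c, iv.start, iv.end) for c, iv in sorted(ann.centromeres.items())],
        columns=["chrom", "start", "end"],
    )
    cent.to_csv(out / "centromeres.tsv", sep="\t", index=False)

    gene_counts, te_counts, truth = gen_counts(sim, ann)
    write_counts_tsv(gene_counts, out / "gene_counts.tsv", out / "samples.tsv")
    write_counts_tsv(te_counts, out / "te_counts.tsv", out / "samples.tsv")
    pd.DataFrame(
        [(g, c) for g, c in sorted(truth["planted_class"].items())],
        columns=["gene_id", "planted_class"],
    ).to_csv(out / "truth_gene_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t, tid) for t, s in truth["activated"].items() for tid in sorted(s)],
        columns=["tissue", "te_id"],
    ).to_csv(out / "truth_activated_tes.tsv", sep="\t", index=False)

    ears = gen_ear_counts(sim)
    write_ear_table(ears, out / "ear_counts.tsv")

    fert, census = gen_phenotypes(sim)
    pd.DataFrame(
        [[g] + [fert.groups[g][c] for c in OUTCOME_COLUMNS] for g in sorted(fert.groups)],
        columns=["group"] + OUTCOME_COLUMNS,
    ).set_index("group").to_csv(out / "fertilization.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "ear_id": c.ear_id,
                "genotype_group": c.genotype_group,
                "n_small": c.n_small,
                "n_normal": c.n_normal,
                "seedless_area_pct": c.seedless_area_pct,
            }
            for c in census
        ]
    ).to_csv(out / "seed_census.tsv", sep="\t", index=False)
    return [
        "genes.gff3", "tes.gff3", "centromeres.tsv", "gene_counts.tsv", "te_counts.tsv",
        "samples.tsv", "truth_gene_classes.tsv", "truth_activated_tes.tsv",
        "ear_counts.tsv", "fertilization.tsv", "seed_census.tsv",
    ]


def _load_annotation(out: Path):
    return read_gff3(out / "genes.gff3", out / "tes.gff3", out / "centromeres.tsv")


def _cmd_diffexpr(out: Path, config: PipelineConfig) -> list:
    _require(out, "te_counts.tsv", "samples.tsv", "genes.gff3", "tes.gff3")
    ann = _load_annotation(out)
    te_counts = read_counts_tsv(out / "te_counts.tsv", out / "samples.tsv")
    prox, _ = classify_proximity(ann, config.proximity_bp)
    distal = [t for t in te_counts.feature_ids if prox.get(t) == "distal"]
    idx = [te_counts.feature_ids.index(t) for t in distal]
    sub = type(te_counts)(
        feature_ids=distal,
        samples=te_counts.samples,
        values=te_counts.values[idx, :],
    )
    artifacts = []
    for tissue in config.target_tissues:
        res = nb_differential(
            sub, config.reference_tissue, tissue, alpha=config.alpha,
            drop_samples=config.drop_samples,
        )
        name = f"de_{tissue}.tsv"
        write_de_tsv(res, out / name)
        artifacts.append(name)
    return artifacts


def _read_de(out: Path, tissue: str):
    from .te_expression import DEResult

    df = pd.read_csv(out / f"de_{tissue}.tsv", sep="\t")
    return [
        DEResult(
            str(r["feature_id"]),
            float(r["log2_fold_change"]),
            None if pd.isna(r["p_value"]) else float(r["p_value"]),
            None if pd.isna(r["p_adjusted"]) else float(r["p_adjusted"]),
            str(r["direction"]),
        )
        for _, r in df.iterrows()
    ]


def _cmd_te_classify(out: Path, config: PipelineConfig) -> list:
    _require(out, "te_counts.tsv", "samples.tsv")
    for tissue in config.target_tissues:
        if not (out / f"de_{tissue}.tsv").exists():
            _cmd_diffexpr(out, config)
            break
    ann = _load_annotation(out)
    te_counts = read_counts_tsv(out / "te_counts.tsv", out / "samples.tsv")
    de_by_tissue = {t: _read_de(out, t) for t in config.target_tissues}
    cats = categorize_tes(
        ann, te_counts, de_by_tissue, min_total=config.min_total, alpha=config.alpha,
        proximity_threshold_bp=config.proximity_bp,
    )
    pd.DataFrame(
        [{"te_id": c.te_id, "category": c.category} for c in cats]
    ).to_csv(out / "te_categories.tsv", sep="\t", index=False)
    return ["te_categories.tsv"]


def _cmd_coexpress(out: Path, config: PipelineConfig) -> list:
    _require(out, "gene_counts.tsv", "samples.tsv")
    ann = _load_annotation(out)
    gene_counts = read_counts_tsv(out / "gene_counts.tsv", out / "samples.tsv")
    expr = expression_from_counts(gene_counts, ann)
    _, gene_to_tes = classify_proximity(ann, config.proximity_bp)
    artifacts = []
    assoc_rows = []
    for tissue in config.coexpression_tissues:
        if not (out / f"de_{tissue}.tsv").exists():
            _cmd_diffexpr(out, config)
        de = _read_de(out, tissue)
        profile = bin_and_count(
            expr, tissue, de, gene_to_tes, n_top=config.n_top, bin_size=config.bin_size
        )
        name = f"bin_profile_{tissue}.tsv"
        profile.to_frame().to_csv(out / name, sep="\t", index=False)
        artifacts.append(name)
        for a in bin_association(profile):
            assoc_rows.append(
                {
                    "tissue": a.tissue,
                    "direction": a.direction,
                    "count_type": a.count_type,
                    "tau": a.tau,
                    "p_value": a.p_value,
                }
            )
    pd.DataFrame(assoc_rows).to_csv(out / "bin_association.tsv", sep="\t", index=False)
    artifacts.append("bin_association.tsv")
    return artifacts


def _cmd_classify_genes(out: Path, config: PipelineConfig) -> list:
    _require(out, "gene_counts.tsv", "samples.tsv")
    ann = _load_annotation(out)
    gene_counts = read_counts_tsv(out / "gene_counts.tsv", out / "samples.tsv")
    expr = expression_from_counts(gene_counts, ann)
    classes = assign_classes(
        expr, quantile=config.top_quantile, high_threshold_log2=config.high_log2fpkm
    )
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "class": c.gene_class,
                "fpkm_mp": c.fpkm_mp,
                "fpkm_sc": c.fpkm_sc,
                "fpkm_seedling": c.fpkm_seedling,
                "high_flag": c.very_high,
            }
            for c in classes
        ]
    ).to_csv(out / "gene_classes.tsv", sep="\t", index=False)
    return ["gene_classes.tsv"]


def _cmd_transmission(out: Path, config: PipelineConfig) -> list:
    _require(out, "ear_counts.tsv")
    datasets = read_ear_table(out / "ear_counts.tsv")
    qc_rows = []
    kept = []
    for ds in datasets:
        filtered, report = qc_ears(ds)
        qc_rows.extend(report)
        if filtered is not None:
            kept.append(filtered)
    pd.DataFrame(qc_rows, columns=["allele_id", "ear_id", "reason", "detail"]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False
    )
    artifacts = ["qc_report.tsv"]
    for direction in ("male", "female"):
        res = test_all_alleles(
            kept, direction=direction, phi_pooling=config.phi_pooling, alpha=config.alpha
        )
        name = f"transmission_{direction}.tsv"
        results_frame(res).to_csv(out / name, sep="\t", index=False)
        artifacts.append(name)
    return artifacts


def _cmd_phenotype(out: Path, config: PipelineConfig) -> list:
    _require(out, "fertilization.tsv", "seed_census.tsv")
    fert = read_fertilization_table(out / "fertilization.tsv")
    groups = sorted(fert.groups)
    rows = []
    if len(groups) >= 2:
        classification, res = fertilization_outcome_test(fert, groups[0], groups[1])
        rows.append(
            {
                "test": "fertilization_outcome",
                "detail": json.dumps(classification),
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    census = read_census_table(out / "seed_census.tsv")
    census_groups = sorted({c.genotype_group for c in census})
    controls = [g for g in census_groups if g.startswith("control")]
    treatments = [g for g in census_groups if g not in controls]
    if controls and treatments:
        for (t, c), res in census_tests(census, treatments, controls).items():
            rows.append(
                {
                    "test": f"census_{t}_vs_{c}",
                    "detail": "small_fraction welch t",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    pd.DataFrame(rows).to_csv(out / "phenotype_tests.tsv", sep="\t", index=False)
    return ["phenotype_tests.tsv"]


def _cmd_report(out: Path, config: PipelineConfig) -> list:
    sections = []
    for name in sorted(out.glob("*.tsv")):
        if name.name.startswith("truth_"):
            continue
        df = pd.read_csv(name, sep="\t")
        sections.append(f"## {name.name} ({len(df)} rows)\n\n{df.head(10).to_string()}\n")
    (out / "report.md").write_text("\n".join(sections) or "no artifacts yet\n")
    return ["report.md"]
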