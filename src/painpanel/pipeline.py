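"""End-to-end orchestration: panel -> variants -> ORA -> knowledge reduction.

Every stage is a thin call into the library modules, so each can also be
run standalone (the CLI exposes one subcommand per stage) with identical
results.  The report collects every number the run produced together with
the configuration that produced it, so a rerun on identical inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

from . import enrichment, reduction, variants
from .ontology import (OntologyDAG, parse_obo, propagate, read_annotations,
                       read_gene_list)

logger = logging.getLogger(__name__)


def load_packaged_panel() -> variants.GenePanel:
    """The packaged 72-gene panel table (29-gene subset 1, 50-gene subset 2,
    7 shared genes)."""
    entries = []
    table = resources.files("painpanel").joinpath("data/panel_table1.tsv")
    with table.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_symbol"):
                continue
            gene, labels = line.split("\t")
            entries.append((gene.upper(), frozenset(labels.split(","))))
    return variants.GenePanel(entries=entries)


@dataclass
class PipelineReport:
    """Machine-readable record of one full run."""

    seed: int | None = None
    config: dict = field(default_factory=dict)
    config_hash: str = ""
    panel_summary: dict = field(default_factory=dict)
    variant_summary: dict = field(default_factory=dict)
    functional_summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [f"painpanel report (config {self.config_hash})"]
        for title, section in (("Panel", self.panel_summary),
                               ("Variants", self.variant_summary),
                               ("Functional genomics", self.functional_summary)):
            if section:
                lines.append(f"\n== {title} ==")
                for key, value in section.items():
                    lines.append(f"  {key}: {value}")
        return "\n".join(lines) + "\n"


def _hash_config(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_panel_stage(subset1, subset2) -> dict:
    panel = variants.assemble_panel(subset1, subset2)
    return panel.summary()


def run_variant_stage(
    vcf_path=None,
    gene_model_path=None,
    variant_records=None,
    panel_genes=(),
    hwe_alpha: float = 0.05,
    hwe_method: str = "fisher_expected",
    padding: int = 25,
) -> dict:
    """Ingest + classify variants, apply the HWE filter, tabulate locations
    and correlate per-gene counts with read gene length."""
    if variant_records is None:
        variant_records = variants.read_vcf(vcf_path)
    models = variants.read_gene_models(gene_model_path, padding=padding) \
        if gene_model_path else []
    for v in variant_records:
        if v.location is None:
            variants.classify_location(v, models)

    kept, dropped = [], 0
    for v in variant_records:
        res = variants.hwe_filter(v.genotype_counts, alpha=hwe_alpha,
                                  method=hwe_method)
        if res.retained:
            kept.append(v)
        else:
            dropped += 1

    table = variants.variant_location_table(kept)
    summary = {
        "n_input": len(variant_records),
        "hwe_dropped": dropped,
        "location_counts": table["by_class"],
        "total_variants": table["total"],
        "zero_variant_genes": variants.zero_variant_genes(
            table["per_gene"], panel_genes),
    }

    if models:
        lengths, counts = [], []
        read_len = {m.gene_symbol: sum(e - s for s, e in m.cds_exons)
                    + sum(e - s for s, e in m.utr5)
                    + sum(e - s for s, e in m.utr3) or (m.span[1] - m.span[0])
                    for m in models}
        for gene, length in read_len.items():
            lengths.append(length)
            counts.append(table["per_gene"].get(gene, 0))
        if len(lengths) >= 4:
            r, p = variants.percentage_bend_correlation(lengths, counts)
            summary["length_correlation"] = {"r": r, "p_value": p}
    return summary


def run_functional_stage(
    dag: OntologyDAG,
    ann,
    study_genes,
    config: enrichment.ORAConfig | None = None,
    cert_complement: bool = False,
    target_range: tuple[int, int] = (5, 9),
    dot_path=None,
) -> dict:
    """ORA then knowledge reduction; optionally writes the classified DAG
    as DOT."""
    results = enrichment.run_ora(dag, ann, study_genes, config)
    reduced = reduction.reduce_terms(dag, results,
                                     cert_complement=cert_complement,
                                     target_range=target_range)
    if dot_path is not None:
        keep = {t for t, c in reduced["classes"].items() if c != "structural"}
        # include structural connectors: ancestors of any classified node
        connectors = set()
        for t in keep:
            connectors |= dag.ancestors(t)
        Path(dot_path).write_text(
            reduction.to_dot(dag, reduced["classes"], keep | connectors))
    sig = [r for r in results if r.significant]
    return {
        "n_tested_terms": len(results),
        "n_significant": len(sig),
        "n_details": len(reduced["details"]),
        "n_headlines": len(reduced["headlines"]),
        "abc_set_a": reduced["important_headlines"],
        "functional_areas": reduced["areas"],
        "results": results,
        "reduced": reduced,
    }


def run_full(
    obo_path,
    annotation_path,
    study_path,
    background_path=None,
    vcf_path=None,
    gene_model_path=None,
    namespace: str | None = "biological_process",
    ora_config: enrichment.ORAConfig | None = None,
    cert_complement: bool = False,
    target_range: tuple[int, int] = (5, 9),
    hwe_alpha: float = 0.05,
    hwe_method: str = "fisher_expected",
    padding: int = 25,
    seed: int | None = None,
    outdir=None,
) -> PipelineReport:
    """Execute every stage on file inputs and assemble the report.

    A stage failure aborts with the stage name attached to the exception.
    """
    ora_config = ora_config or enrichment.ORAConfig()
    config = {
        "namespace": namespace, "p_threshold": ora_config.p_threshold,
        "correction": ora_config.correction,
        "min_annotated": ora_config.min_annotated,
        "cert_complement": cert_complement, "target_range": list(target_range),
        "hwe_alpha": hwe_alpha, "hwe_method": hwe_method, "padding": padding,
        "seed": seed,
    }
    report = PipelineReport(seed=seed, config=config,
                            config_hash=_hash_config(config))
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "panel"
    try:
        panel = load_packaged_panel()
        report.panel_summary = panel.summary()

        if vcf_path:
            stage = "variants"
            report.variant_summary = run_variant_stage(
                vcf_path=vcf_path, gene_model_path=gene_model_path,
                panel_genes=panel.genes, hwe_alpha=hwe_alpha,
                hwe_method=hwe_method, padding=padding)

        stage = "ora"
        dag = parse_obo(obo_path, namespace=namespace)
        direct = read_annotations(annotation_path)
        background = read_gene_list(background_path) if background_path else None
        ann = propagate(dag, direct, background_genes=background)
        study = read_gene_list(study_path)

        stage = "reduce"
        functional = run_functional_stage(
            dag, ann, study, config=ora_config,
            cert_complement=cert_complement, target_range=target_range,
            dot_path=outdir / "reduced_dag.dot" if outdir else None)
        report.functional_summary = {
            k: v for k, v in functional.items()
            if k not in ("results", "reduced")
        }

        if outdir:
            stage = "report"
            _write_term_tsv(outdir / "ora_results.tsv", functional)
            (outdir / "report.json").write_text(report.to_json())
            (outdir / "report.txt").write_text(report.to_text())
    except Exception as exc:  # re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _write_term_tsv(path, functional: dict) -> None:
    reduced = functional["reduced"]
    scores = reduced["scores"]
    classes = reduced["classes"]
    abc_a = set(reduced["important_headlines"])
    with open(path, "w") as fh:
        fh.write("term_id\tname\tk\tK\tn_set\tN\tp_value\tsignificant\t"
                 "cert\tinfo\trem\tabc_set\tnode_class\n")
        for r in functional["results"]:
            sc = scores.get(r.term_id)
            fh.write("\t".join([
                r.term_id, r.name, str(r.k), str(r.K), str(r.n_set), str(r.N),
                f"{r.p_value:.6g}", str(r.significant),
                f"{sc.cert:.6g}" if sc else "",
                f"{sc.info:.6g}" if sc else "",
                f"{sc.rem:.6g}" if sc else "",
                "A" if r.term_id in abc_a else "",
                classes.get(r.term_id, "structural"),
            ]) + "\n")
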