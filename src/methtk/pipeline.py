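"""Declarative pipeline runner.

A run is described by a YAML config (samples, two groups, per-stage
parameters); stages execute in dependency order

    call -> filter -> summarize -> annotate / dmr -> correlate

with fail-fast validation: every config and file problem is reported
before any computation starts.  A machine-readable manifest (package
version, parameters, input checksums, per-stage status) is written at
the end; with ``resume=True`` a stage whose declared outputs already
exist is skipped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .annotation import aggregate_over_regions, cluster_region_heatmap, per_region_boxplot_tables
from .calling import CallingOptions, call_methylation
from .correlating import correlate_pairs, correlation_report
from .dmr import SegmentationParams, call_dmrs, dmr_statistics
from .filtering import FilterSpec, distribution_summaries, filter_records
from .grouping import (
    build_sample_matrix,
    genomewide_binned_means,
    overview_statistics,
    summarize_groups,
)
from .io import (
    read_bed,
    read_expression_table,
    read_methylation_vcf,
    read_pairs_table,
    write_bedgraph,
    write_dmr_bed,
    write_dmr_table,
    write_methylation_vcf,
)

STAGES = ("call", "filter", "summarize", "annotate", "dmr", "correlate")


class ConfigError(ValueError):
    """One or more validation failures, all collected before raising."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    config.setdefault("_config_dir", str(Path(path).parent))
    return config


def validate_config(config: dict) -> list[str]:
    problems: list[str] = []
    base = Path(config.get("_config_dir", "."))

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    if "output_dir" not in config:
        problems.append("missing required key: output_dir")
    samples = config.get("samples")
    if not isinstance(samples, dict) or not samples:
        problems.append("samples: must map sample names to methylation VCF paths")
        samples = {}
    for name, path in samples.items():
        if not resolve(path).exists():
            problems.append(f"samples.{name}: file not found: {path}")
    groups = config.get("groups", {})
    for g in ("group1", "group2"):
        members = groups.get(g, [])
        if not members:
            problems.append(f"groups.{g}: must list at least one sample")
        for m in members:
            if m not in samples:
                problems.append(f"groups.{g}: unknown sample {m!r}")
    if set(groups.get("group1", [])) & set(groups.get("group2", [])):
        problems.append("groups: group1 and group2 overlap")
    call_cfg = config.get("call")
    if call_cfg:
        for key in ("bam", "reference"):
            if key not in call_cfg:
                problems.append(f"call.{key}: required when the call stage is configured")
            elif not resolve(call_cfg[key]).exists():
                problems.append(f"call.{key}: file not found: {call_cfg[key]}")
    ann = config.get("annotate")
    if ann:
        if "bed" not in ann:
            problems.append("annotate.bed: required when the annotate stage is configured")
        elif not resolve(ann["bed"]).exists():
            problems.append(f"annotate.bed: file not found: {ann['bed']}")
    corr = config.get("correlate")
    if corr:
        for key in ("expression", "pairs"):
            if key not in corr:
                problems.append(f"correlate.{key}: required")
            elif not resolve(corr[key]).exists():
                problems.append(f"correlate.{key}: file not found: {corr[key]}")
    return problems


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, resume: bool = False, make_plots: bool = True) -> dict:
    problems = validate_config(config)
    if problems:
        raise ConfigError(problems)
    base = Path(config.get("_config_dir", "."))

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    out = Path(config["output_dir"])
    if not out.is_absolute():
        out = base / out
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in config.items() if not k.startswith("_")},
        "inputs": {},
        "stages": {},
    }
    sample_paths = {n: resolve(p) for n, p in config["samples"].items()}
    for name, path in sample_paths.items():
        manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage_done(outputs: list[Path]) -> bool:
        return resume and all(p.exists() for p in outputs)

    # ---- call (optional) ------------------------------------------------
    if config.get("call"):
        import pyfaidx

        call_cfg = config["call"]
        called_vcf = out / "called.vcf"
        if stage_done([called_vcf]):
            manifest["stages"]["call"] = "skipped (resume)"
        else:
            opts = CallingOptions(
                min_base_quality=call_cfg.get("min_base_quality", 20),
                min_mapping_quality=call_cfg.get("min_mapping_quality", 10),
                trim_ends=call_cfg.get("trim_ends", 0),
                clip_overlap=call_cfg.get("clip_overlap", True),
            )
            ref = pyfaidx.Fasta(str(resolve(call_cfg["reference"])))
            records = call_methylation(resolve(call_cfg["bam"]), ref, opts)
            write_methylation_vcf(records, called_vcf)
            manifest["stages"]["call"] = "completed"

    # ---- filter ---------------------------------------------------------
    filt_cfg = config.get("filter", {})
    spec = FilterSpec(
        min_coverage=filt_cfg.get("min_coverage", 10),
        max_coverage=filt_cfg.get("max_coverage"),
        max_coverage_quantile=filt_cfg.get("max_coverage_quantile", 0.999),
        contexts=frozenset(filt_cfg.get("contexts", ["CG"])),
    )
    filtered_paths = {n: out / f"{n}.filtered.vcf" for n in sample_paths}
    if stage_done(list(filtered_paths.values())):
        manifest["stages"]["filter"] = "skipped (resume)"
        filtered = {n: read_methylation_vcf(p) for n, p in filtered_paths.items()}
    else:
        filtered = {}
        for name, path in sample_paths.items():
            records = read_methylation_vcf(path)
            kept, report = filter_records(records, spec)
            filtered[name] = kept
            write_methylation_vcf(kept, filtered_paths[name])
            write_bedgraph((r for r in kept if r.coverage > 0), out / f"{name}.filtered.bedgraph")
            with open(out / f"{name}.filter_report.tsv", "w") as fh:
                fh.write("\n".join(report.to_lines()) + "\n")
            if make_plots:
                from .plots import plot_filter_distributions

                plot_filter_distributions(
                    *distribution_summaries(records, kept), out / f"{name}.filter_qc"
                )
        manifest["stages"]["filter"] = "completed"

    # ---- summarize ------------------------------------------------------
    summ_cfg = config.get("summarize", {})
    names = list(sample_paths)
    matrix = build_sample_matrix(
        [filtered[n] for n in names],
        names,
        min_coverage_per_sample=summ_cfg.get("min_coverage", 10),
    )
    group1 = config["groups"]["group1"]
    group2 = config["groups"]["group2"]
    summary = summarize_groups(
        matrix, group1, group2, min_samples=summ_cfg.get("min_samples", 1)
    )
    summary_outputs = [out / "group_diff.bedgraph", out / "binned_means.tsv"]
    if stage_done(summary_outputs):
        manifest["stages"]["summarize"] = "skipped (resume)"
    else:
        entries = [
            (p[0], p[1], d) for p, d in zip(summary.positions, summary.diff)
        ]
        write_bedgraph(entries, out / "group_diff.bedgraph")
        for label, means in (("group1", summary.mean_g1), ("group2", summary.mean_g2)):
            write_bedgraph(
                [(p[0], p[1], m) for p, m in zip(summary.positions, means)],
                out / f"{label}_mean.bedgraph",
            )
        genomewide_binned_means(
            matrix, bin_size=summ_cfg.get("bin_size", 1_000_000)
        ).to_csv(out / "binned_means.tsv", sep="\t", index=False)
        if matrix.n_samples >= 2:
            bundle = overview_statistics(matrix, summary)
            if make_plots:
                from .plots import plot_overview

                plot_overview(bundle, out / "overview")
        manifest["stages"]["summarize"] = "completed"

    # ---- annotate (optional) --------------------------------------------
    if config.get("annotate"):
        ann_cfg = config["annotate"]
        ann_out = out / "annotation_means.tsv"
        if stage_done([ann_out]):
            manifest["stages"]["annotate"] = "skipped (resume)"
        else:
            regions = read_bed(resolve(ann_cfg["bed"]))
            agg = aggregate_over_regions(
                matrix,
                regions,
                min_positions=ann_cfg.get("min_positions", 3),
                group1=group1,
                group2=group2,
            )
            agg.table.to_csv(ann_out, sep="\t", index_label="region")
            for label, tbl in per_region_boxplot_tables(agg).items():
                tbl.to_csv(out / f"annotation_{label}.tsv", sep="\t")
            if agg.table.shape[0] >= 2 and agg.table.shape[1] >= 2 and make_plots:
                from .plots import plot_annotation_heatmap

                clustering = cluster_region_heatmap(agg.table)
                plot_annotation_heatmap(agg.table, clustering, out / "annotation_heatmap")
            manifest["stages"]["annotate"] = "completed"

    # ---- dmr ------------------------------------------------------------
    dmr_cfg = config.get("dmr", {})
    params = SegmentationParams(
        max_gap=dmr_cfg.get("max_gap", 300),
        min_cpg=dmr_cfg.get("min_cpg", 10),
        min_diff=dmr_cfg.get("min_diff", 0.1),
        max_q=dmr_cfg.get("max_q", 0.05),
        min_length_nt=dmr_cfg.get("min_length_nt"),
    )
    dmr_bed = out / "dmrs.bed"
    dmr_tsv = out / "dmrs.tsv"
    if stage_done([dmr_bed, dmr_tsv]):
        manifest["stages"]["dmr"] = "skipped (resume)"
        from .io import read_dmr_table

        dmrs = read_dmr_table(dmr_tsv)
    else:
        dmrs = call_dmrs(summary, params)
        write_dmr_bed(dmrs, dmr_bed)
        write_dmr_table(dmrs, dmr_tsv)
        with open(out / "dmrs.bedgraph", "w") as fh:
            for d in dmrs:
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.mean_diff:.6f}\n")
        if make_plots:
            from .plots import plot_dmr_statistics

            plot_dmr_statistics(dmr_statistics(dmrs), out / "dmr_stats")
        manifest["stages"]["dmr"] = "completed"

    # ---- correlate (optional) -------------------------------------------
    if config.get("correlate"):
        corr_cfg = config["correlate"]
        corr_out = out / "cdmr_table.tsv"
        if stage_done([corr_out]):
            manifest["stages"]["correlate"] = "skipped (resume)"
        else:
            expression = read_expression_table(resolve(corr_cfg["expression"]))
            pairs = read_pairs_table(resolve(corr_cfg["pairs"]))
            known = {d.name for d in dmrs}
            usable_pairs = [(d, g) for d, g in pairs if d in known]
            records = correlate_pairs(dmrs, matrix, expression, usable_pairs)
            report = correlation_report(records, cutoff=corr_cfg.get("cutoff", 0.8))
            report.to_csv(corr_out, sep="\t", index=False)
            with open(out / "correlations.tsv", "w") as fh:
                fh.write("dmr_id\tgene_id\tpearson_r\tspearman_rho\tn_samples\tflag\n")
                for rec in records:
                    r = "" if rec.pearson_r is None else f"{rec.pearson_r:.6f}"
                    rho = "" if rec.spearman_rho is None else f"{rec.spearman_rho:.6f}"
                    fh.write(
                        f"{rec.dmr_id}\t{rec.gene_id}\t{r}\t{rho}\t{rec.n_samples}\t{rec.flag}\n"
                    )
            manifest["stages"]["correlate"] = "completed"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
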