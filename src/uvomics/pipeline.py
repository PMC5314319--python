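"""End-to-end orchestration of the analysis stages.

Given a run configuration pointing at the input files, the pipeline
executes: gene-level differential acetylation, super-enhancer calling
and comparison, expression classification and DGE x DHA integration,
variant profiling, and the essentiality caller — skipping any stage
whose inputs are absent — and writes per-stage TSVs plus a JSON report
of summary counts.  Two runs with identical inputs and seed produce
identical reports (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import __version__
from .chromatin import compute_dha, dha_table, global_signal_slope, merged_region_signals
from .enrichment import hypergeometric_enrichment, permutation_pvalue, read_gmt
from .expression import (
    compute_dge,
    concordance_matrix,
    group_shift_test,
    integrate,
    integration_table,
)
from .genome import read_gene_annotation, read_peaks
from .superenhancers import annotate_se_genes, call_superenhancers, compare_se_sets
from .variants import (
    annotation_table,
    category_counts,
    classify_variants,
    filter_by_depth,
    intersect_variant_sets,
    mutation_spectrum,
    read_variants,
)

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "genes", "peaks_control", "peaks_uv", "expression", "variants_a", "variants_b",
    "screen_dir", "gene_sets", "out_dir", "seed", "window", "fc_cutoff",
    "stitch_distance", "tss_window", "se_gene_window", "min_depth",
    "n_perm", "consistency_alpha", "specificity_alpha", "screen_is_raw_counts",
}


@dataclass
class RunConfig:
    """Input paths and stage parameters (defaults are the standard values)."""

    out_dir: str = "uvomics_out"
    seed: int = 0
    genes: str | None = None
    peaks_control: str | None = None
    peaks_uv: str | None = None
    expression: str | None = None
    variants_a: str | None = None
    variants_b: str | None = None
    screen_dir: str | None = None
    gene_sets: str | None = None  # GMT for hypergeometric enrichment
    window: int = 10_000
    fc_cutoff: float = 2.0
    stitch_distance: int = 12_500
    tss_window: int = 2500
    se_gene_window: int = 25_000
    min_depth: int = 10
    n_perm: int = 1000
    consistency_alpha: float = 0.1
    specificity_alpha: float = 0.05
    screen_is_raw_counts: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage whose inputs are present; return the report dict."""
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "run_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    annotation = None
    if config.genes:
        annotation = read_gene_annotation(config.genes)

    def stage(name: str, fn, *needs):
        if any(x is None for x in needs):
            log.info("stage %s skipped: inputs absent", name)
            report["stages"][name] = {"skipped": True}
            return None
        t0 = time.monotonic()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise StageError(name, exc) from exc
        log.info("stage %s done in %.1fs", name, time.monotonic() - t0)
        report["stages"].setdefault(name, {})["elapsed_s"] = round(time.monotonic() - t0, 2)
        return out

    peaks_c = read_peaks(config.peaks_control, "control") if config.peaks_control else None
    peaks_u = read_peaks(config.peaks_uv, "uv") if config.peaks_uv else None

    dha_records = None

    def _dha():
        nonlocal dha_records
        dha_records = compute_dha(peaks_c, peaks_u, annotation,
                                  config.window, config.fc_cutoff)
        table = dha_table(dha_records)
        table.to_csv(os.path.join(config.out_dir, "dha.tsv"), sep="\t", index=False)
        merged = merged_region_signals(peaks_c, peaks_u)
        slope = global_signal_slope(merged["control"], merged["uv"])
        counts = table["dha_class"].value_counts().to_dict()
        report["stages"]["dha"] = {
            "n_genes": len(table),
            "classes": {c: int(counts.get(c, 0)) for c in ("up", "down", "none")},
            "global_slope": slope,
        }

    stage("dha", _dha, peaks_c, peaks_u, annotation)

    def _se():
        sets = {}
        for sample, peaks in (("control", peaks_c), ("uv", peaks_u)):
            se_set = call_superenhancers(peaks, annotation, config.stitch_distance,
                                         config.tss_window, sample)
            annotate_se_genes(se_set, annotation, config.se_gene_window)
            sets[sample] = se_set
            rows = [
                f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}\t"
                f"SE_{sample}_{e.rank}\t{e.total_signal:g}\n"
                for e in se_set.superenhancers
            ]
            with open(os.path.join(config.out_dir, f"se_{sample}.bed"), "w") as fh:
                fh.writelines(rows)
        venn = compare_se_sets(sets["control"], sets["uv"])
        report["stages"]["superenhancers"] = {
            "n_se": {s: len(sets[s].superenhancers) for s in sets},
            "n_stitched": {s: len(sets[s].stitched) for s in sets},
            "venn": {k: len(v) for k, v in venn.items()},
        }
        return sets

    stage("superenhancers", _se, peaks_c, peaks_u, annotation)

    integrated = None

    def _expression():
        nonlocal integrated
        import pandas as pd

        expr = pd.read_csv(config.expression, sep="\t")
        dge = compute_dge(expr, fc_cutoff=config.fc_cutoff)
        from collections import Counter

        counts = Counter(r.dge_class for r in dge)
        report["stages"]["dge"] = {
            "n_genes": len(dge),
            "classes": {c: counts.get(c, 0) for c in ("up", "down", "none")},
        }
        if dha_records is None:
            return
        integrated = integrate(dge, dha_records)
        table = integration_table(integrated)
        table.to_csv(os.path.join(config.out_dir, "integration.tsv"), sep="\t", index=False)
        groups = {b: table.loc[table["dha_bin"] == b, "dge_log2fc"].tolist()
                  for b in ("gt1", "lt-1", "mid")}
        shift = group_shift_test(groups)
        shift.to_csv(os.path.join(config.out_dir, "group_shift.tsv"), sep="\t", index=False)
        conc = concordance_matrix(integrated)
        conc.to_csv(os.path.join(config.out_dir, "concordance.tsv"), sep="\t")
        report["stages"]["integration"] = {
            "n_genes": len(integrated),
            "positive": int(sum(r.concordance == "positive" for r in integrated)),
            "inverse": int(sum(r.concordance == "inverse" for r in integrated)),
            "group_shift": shift.to_dict(orient="records"),
        }

    stage("expression", _expression, config.expression)

    def _variants():
        va = filter_by_depth(read_variants(config.variants_a), config.min_depth)
        vb = filter_by_depth(read_variants(config.variants_b), config.min_depth)
        common = intersect_variant_sets(va, vb)
        entry = {
            "n_a": len(va),
            "n_b": len(vb),
            "n_common": len(common),
            "spectrum_common": mutation_spectrum(common),
        }
        if annotation is not None:
            ann = classify_variants(common, annotation)
            annotation_table(ann).to_csv(
                os.path.join(config.out_dir, "variants_common.tsv"), sep="\t", index=False
            )
            entry["categories_common"] = category_counts(ann)
        report["stages"]["variants"] = entry

    stage("variants", _variants, config.variants_a, config.variants_b)

    def _enrichment():
        from .enrichment import RankedList

        pathways = read_gmt(config.gene_sets)
        table = integration_table(integrated)
        universe = table["gene_id"].tolist()
        pathways = {name: [g for g in members if g in set(universe)]
                    for name, members in pathways.items()}
        pathways = {n: m for n, m in pathways.items() if m}
        query = table.loc[table["dge_class"] == "up", "gene_id"].tolist()
        hyper = hypergeometric_enrichment(query, pathways, universe)
        hyper.to_csv(os.path.join(config.out_dir, "enrichment_hypergeom.tsv"),
                     sep="\t", index=False)
        ranked = RankedList.from_scores(
            dict(zip(table["gene_id"], table["dge_log2fc"])))
        ks_rows = []
        for name, members in pathways.items():
            if 0 < len(members) < len(universe):
                res = permutation_pvalue(ranked, members, config.n_perm, config.seed)
                ks_rows.append({"gene_set": name, "es": res.es, "p_perm": res.p_perm,
                                "n_perm": res.n_perm, "seed": res.seed})
        if ks_rows:
            import pandas as pd

            pd.DataFrame(ks_rows).to_csv(
                os.path.join(config.out_dir, "enrichment_ks.tsv"), sep="\t", index=False)
        report["stages"]["enrichment"] = {
            "n_gene_sets": len(pathways),
            "min_p_bonferroni": float(hyper["p_bonferroni"].min()) if len(hyper) else None,
        }

    stage("enrichment", _enrichment, config.gene_sets, integrated)

    def _essentiality():
        from .essentiality import run_essentiality_pipeline
        from .simulate import read_screen

        screen = read_screen(config.screen_dir)
        result = run_essentiality_pipeline(
            screen, raw_counts=config.screen_is_raw_counts, seed=config.seed,
            consistency_alpha=config.consistency_alpha,
            specificity_alpha=config.specificity_alpha,
        )
        result.to_csv(os.path.join(config.out_dir, "essentiality.tsv"), sep="\t", index=False)
        report["stages"]["essentiality"] = {
            "n_genes": int(len(result)),
            "n_consistent": int(result["passes"].sum()),
            "n_skin_specific": int(result["skin_specific"].sum()),
        }

    stage("essentiality", _essentiality, config.screen_dir)

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
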