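"""End-to-end orchestration: simulate -> classify -> annotate -> burden-test
-> integrations -> sv-compare -> validate-traces.

Each stage reads only files named in the cohort manifest and writes its
outputs under the run directory, so stages are independently re-runnable;
a JSON report records the seed, parameters and per-stage record counts.
Re-running with the same configuration reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import annotation, callset, integration, io, stats, svcompare, traces
from .intervals import read_bed
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("mutburden")

ALL_STAGES = ("simulate", "classify", "annotate", "burden", "integrations",
              "sv", "traces")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple = ALL_STAGES
    contrasts: tuple = ((-2, 1, 1), (1, -2, 1), (1, 1, -2))
    min_variants: int = 10
    alpha: float = 0.05
    target_power: float = 0.80
    unique_mode: str = "lenient"
    require_tranche: bool = True
    min_support: int = 5
    cluster_window: int = 500
    sv_cutoff: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        for key in ("genome_spec", "method_names", "unique_rate_per_method",
                    "caller_sensitivity", "caller_fpr"):
            if key in cohort_raw and isinstance(cohort_raw[key], list):
                cohort_raw[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in cohort_raw[key]
                )
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        return cls(cohort=CohortConfig(**cohort_raw), **raw)


def _timed(stage):
    def wrap(fn):
        def inner(ctx, *a, **kw):
            t0 = time.perf_counter()
            try:
                result = fn(ctx, *a, **kw)
            except Exception as exc:   # noqa: BLE001 - rewrapped with stage name
                raise StageError(stage, exc) from exc
            log.info("stage=%s elapsed=%.2fs counts=%s", stage,
                     time.perf_counter() - t0, ctx["counts"].get(stage))
            return result
        return inner
    return wrap


@_timed("simulate")
def _stage_simulate(ctx):
    ds = generate_cohort(ctx["config"].cohort)
    io.write_cohort(ds, ctx["cohort_dir"])
    ctx["counts"]["simulate"] = {
        "truth_variants": int(len(ds.truth_variants)),
        "hc_calls": int(len(ds.hc_calls)),
        "mutect_calls": int(sum(len(df) for df in ds.mutect_calls.values())),
        "integration_pairs": int(len(ds.integration_pairs)),
        "sv_calls": len(ds.sv_calls),
        "traces": len(ds.traces),
    }


@_timed("classify")
def _stage_classify(ctx):
    cfg = ctx["config"]
    cdir = Path(ctx["cohort_dir"])
    manifest = io.load_manifest(cdir)
    hc = io.read_multisample_vcf(cdir / manifest["files"]["hc_vcf"])
    mutect = {
        s: io.read_pairwise_vcf(cdir / fname)
        for s, fname in sorted(manifest["files"]["mutect_vcfs"].items())
    }
    merged = callset.merge_caller_outputs(hc, mutect)
    all_ids = [manifest["parental_sample_id"]] + manifest["line_sample_ids"]
    unique = callset.identify_unique_variants(
        merged, all_ids, manifest["parental_sample_id"], mode=cfg.unique_mode)
    uniq_keys = {
        (s, k.chrom, k.pos, k.ref, k.alt) for s, keys in unique.items() for k in keys
    }
    mask = [
        (r.sample_id, r.chrom, r.pos, r.ref, r.alt) in uniq_keys
        for r in merged.itertuples()
    ]
    unique_calls = merged[np.array(mask, dtype=bool)]

    lowc = read_bed(cdir / manifest["files"]["tracks"]["low_complexity"]) \
        if "low_complexity" in manifest["files"]["tracks"] else None
    known_df = pd.read_csv(cdir / manifest["files"]["known_variants"], sep="\t")
    known = set(zip(known_df["chrom"], known_df["pos"].astype(int),
                    known_df["ref"], known_df["alt"]))
    filtered = callset.apply_exclusion_filters(
        unique_calls, low_complexity=lowc, known_variants=known,
        require_tranche=cfg.require_tranche)
    classified = callset.classify_calls(filtered)
    out = Path(cfg.outdir) / "results"
    out.mkdir(parents=True, exist_ok=True)
    classified.to_csv(out / "unique_variants.tsv", sep="\t", index=False)
    ctx["classified"] = classified
    ctx["manifest"] = manifest
    ctx["counts"]["classify"] = {
        "merged_records": int(len(merged)),
        "unique_records": int(len(unique_calls)),
        "after_filters": int(len(filtered)),
        "set1": int((classified["caller_set"] == "SET1").sum()),
        "set2": int((classified["caller_set"] == "SET2").sum()),
        "set3": int((classified["caller_set"] == "SET3").sum()),
    }


@_timed("annotate")
def _stage_annotate(ctx):
    cfg = ctx["config"]
    cdir = Path(ctx["cohort_dir"])
    manifest = ctx["manifest"]
    tracks = {
        cat: read_bed(cdir / fname)
        for cat, fname in sorted(manifest["files"]["tracks"].items())
    }
    pred = pd.read_csv(cdir / manifest["files"]["predictors"], sep="\t")
    pred_map = {
        (r.chrom, r.pos, r.ref, r.alt): r
        for r in pred.itertuples()
    } if len(pred) else {}

    set1 = ctx["classified"][ctx["classified"]["caller_set"] == "SET1"]
    records = []
    chrom_names = {c for c, _ in ctx["config"].cohort.genome_spec}
    for r in set1.itertuples():
        p = pred_map.get((r.chrom, r.pos, r.ref, r.alt))
        records.append(annotation.categorize_variant(
            callset.VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
            r.sample_id, tracks,
            predictor_labels=(p.condel, p.polyphen, p.sift) if p else None,
            cadd_phred=float(p.cadd_phred) if p is not None else None,
            known_chroms=chrom_names,
        ))
    table = annotation.build_burden_table(
        records, manifest["line_sample_ids"], manifest["method_of"])
    out = Path(cfg.outdir) / "results"
    burden = table.counts.copy()
    burden["total"] = table.totals
    burden.insert(0, "method", [table.method_of[s] for s in burden.index])
    burden.to_csv(out / "burden_table.tsv", sep="\t")
    ctx["burden"] = table
    ctx["counts"]["annotate"] = {
        "annotated_records": len(records),
        "categories": len(table.categories),
    }


@_timed("burden")
def _stage_burden(ctx):
    cfg = ctx["config"]
    table = ctx["burden"]
    labels = table.labels()
    methods = list(dict.fromkeys(labels))
    reportable = stats.filter_reportable(table.counts, cfg.min_variants)
    dropped = [c for c in table.categories if c not in reportable]
    rows, report_cats = [], {}
    rates = (stats.relative_rates(table.counts, table.totals)
             if (table.totals > 0).all() else None)
    for cat in reportable + ["total"]:
        values = (table.totals if cat == "total" else table.counts[cat]).to_numpy(dtype=float)
        perm = stats.permutation_anova(values, labels, category=cat)
        by_method = table.values_by_method(cat)
        groups = [by_method[m] for m in methods]
        power = stats.sample_size_for_power(groups, cfg.alpha, cfg.target_power) \
            if not np.allclose(np.var([np.mean(g) for g in groups]), 0) else None
        row = {"category": cat, "F_obs": perm.F_obs, "p_permutation": perm.p_value,
               "n_partitions": perm.n_partitions,
               "n_for_power": power.n_per_group if power else None}
        if rates is not None and cat != "total":
            rperm = stats.permutation_anova(
                rates[cat].to_numpy(dtype=float), labels, category=cat)
            row["p_permutation_rate"] = rperm.p_value
        contrasts = {}
        for c in cfg.contrasts:
            res = stats.contrast_test(groups, c)
            tag = ",".join(str(int(x)) for x in c)
            row[f"estimate({tag})"] = res.estimate
            row[f"t({tag})"] = res.t
            row[f"p({tag})"] = res.p_parametric
            row[f"p_perm({tag})"] = res.p_permutation
            contrasts[tag] = {
                "estimate": res.estimate, "se": res.se, "t": res.t,
                "df": res.df, "p_parametric": res.p_parametric,
                "p_permutation": res.p_permutation,
            }
        rows.append(row)
        report_cats[cat] = {
            "F_obs": perm.F_obs, "p_permutation": perm.p_value,
            "contrasts": contrasts,
            "n_for_power": power.n_per_group if power else None,
        }
    out = Path(cfg.outdir) / "results"
    pd.DataFrame(rows).to_csv(out / "stats_report.tsv", sep="\t", index=False)
    ctx["stats_report"] = {"categories": report_cats, "dropped_min_variants": dropped}
    ctx["counts"]["burden"] = {"tested": len(reportable) + 1, "dropped": len(dropped)}


@_timed("integrations")
def _stage_integrations(ctx):
    cfg = ctx["config"]
    cdir = Path(ctx["cohort_dir"])
    manifest = ctx["manifest"]
    pairs = pd.read_csv(cdir / manifest["files"]["integration_pairs"], sep="\t")
    gene_track = read_bed(cdir / manifest["files"]["tracks"]["gene"]) \
        if "gene" in manifest["files"]["tracks"] else None
    rows = []
    n_sites = 0
    for sample in sorted(pairs["sample_id"].unique()) if len(pairs) else []:
        sub = pairs[pairs["sample_id"] == sample]
        sites = integration.detect_integration_sites(
            sub, min_support=cfg.min_support, cluster_window=cfg.cluster_window)
        if gene_track is not None:
            sites = integration.annotate_sites(sites, gene_track)
        for s in sites:
            rows.append({"sample_id": sample, "chrom": s.chrom,
                         "start": s.window[0], "end": s.window[1],
                         "virus": s.virus, "left_support": s.left_support,
                         "right_support": s.right_support,
                         "annotation": s.annotation, "gene": s.gene})
        n_sites += len(sites)
    out = Path(cfg.outdir) / "results"
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "virus",
                                "left_support", "right_support", "annotation",
                                "gene"]).to_csv(out / "integration_sites.tsv",
                                                sep="\t", index=False)
    ctx["counts"]["integrations"] = {"sites": n_sites}


@_timed("sv")
def _stage_sv(ctx):
    cfg = ctx["config"]
    cdir = Path(ctx["cohort_dir"])
    manifest = ctx["manifest"]
    calls, _support = io.read_sv_tables(
        cdir / manifest["files"]["sv_calls"], cdir / manifest["files"]["sv_support"])
    consensus_by_sample = {}
    for sample in manifest["sv_samples"]:
        split = [c for c in calls if c.sample_id == sample and c.algorithm == "split"]
        glob = [c for c in calls if c.sample_id == sample and c.algorithm == "global"]
        consensus_by_sample[sample] = svcompare.consensus_calls(
            split, glob, cutoff=cfg.sv_cutoff)
    specific = svcompare.find_cell_line_specific(
        consensus_by_sample, cutoff=cfg.sv_cutoff) \
        if len(consensus_by_sample) >= 2 else []
    rows = []
    for c in specific:
        passed, reason = (svcompare.curate_specific(c, c.molecule_support)
                          if c.molecule_support else (False, "no_support_data"))
        rows.append({"sample_id": c.sample_id, "chrom": c.chrom, "start": c.start,
                     "end": c.end, "size": c.size, "svtype": c.svtype,
                     "call_id": c.call_id, "curated_pass": passed, "reason": reason})
    out = Path(cfg.outdir) / "results"
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "size",
                                "svtype", "call_id", "curated_pass", "reason"]
                 ).to_csv(out / "sv_specific.tsv", sep="\t", index=False)
    ctx["counts"]["sv"] = {
        "consensus": {s: len(v) for s, v in sorted(consensus_by_sample.items())},
        "candidate_specific": len(specific),
        "curated_pass": int(sum(r["curated_pass"] for r in rows)),
    }


@_timed("traces")
def _stage_traces(ctx):
    cfg = ctx["config"]
    cdir = Path(ctx["cohort_dir"])
    manifest = ctx["manifest"]
    windows = io.read_traces_tsv(cdir / manifest["files"]["traces"])
    truth = pd.read_csv(cdir / manifest["files"]["trace_truth"], sep="\t")
    truth_map = {r.variant_id: r for r in truth.itertuples()}
    rows = []
    for w in windows:
        t = truth_map.get(w.variant_id)
        if t is None:
            continue
        call = traces.call_trace_variant(w, t.alt_channel)
        rows.append({"variant_id": w.variant_id, "genotype": t.genotype,
                     "called_variant": call.is_variant,
                     "background_mean": call.background_mean,
                     "background_sd": call.background_sd,
                     "threshold": call.threshold,
                     "center_amplitude": call.center_amplitude})
    df = pd.DataFrame(rows, columns=["variant_id", "genotype", "called_variant",
                                     "background_mean", "background_sd",
                                     "threshold", "center_amplitude"])
    out = Path(cfg.outdir) / "results"
    df.to_csv(out / "trace_validation.tsv", sep="\t", index=False)
    het = df[df["genotype"] == "het"]
    hom = df[df["genotype"] == "hom"]
    ctx["counts"]["traces"] = {
        "het_called": int(het["called_variant"].sum()), "het_total": int(len(het)),
        "hom_called": int(hom["called_variant"].sum()), "hom_total": int(len(hom)),
    }


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "annotate": _stage_annotate,
    "burden": _stage_burden,
    "integrations": _stage_integrations,
    "sv": _stage_sv,
    "traces": _stage_traces,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the report dictionary (also
    written to <outdir>/report.json)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = {"config": config, "cohort_dir": outdir / "cohort", "counts": {}}
    for stage in ALL_STAGES:
        if stage in config.stages:
            _STAGE_FNS[stage](ctx)
    report = {
        "seed": config.cohort.seed,
        "parameters": {
            "cohort": dataclasses.asdict(config.cohort),
            "contrasts": [list(c) for c in config.contrasts],
            "min_variants": config.min_variants,
            "alpha": config.alpha,
            "target_power": config.target_power,
            "unique_mode": config.unique_mode,
            "min_support": config.min_support,
            "cluster_window": config.cluster_window,
            "sv_cutoff": config.sv_cutoff,
        },
        "counts": ctx["counts"],
        "statistics": ctx.get("stats_report"),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
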