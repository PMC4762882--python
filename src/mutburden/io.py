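"""File formats: minimal VCF v4.2 writing, cyvcf2-backed reading, BED/TSV
tables and the YAML cohort manifest.

The multisample (population-caller) VCF carries per-sample GT:DP:AD and a
TRANCHE filter for recalibration failures; the per-line pairwise-caller VCFs
carry the KEEP judgment as FILTER PASS and REJECT otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from cyvcf2 import VCF

from .intervals import write_bed
from .synthetic import CohortDataset
from .traces import CHANNELS, N_FLANK, TraceWindow

__all__ = [
    "write_multisample_vcf", "write_pairwise_vcf",
    "read_multisample_vcf", "read_pairwise_vcf",
    "write_traces_tsv", "read_traces_tsv",
    "write_sv_tables", "read_sv_tables",
    "write_cohort", "load_manifest",
]

MISSING = -1


def _vcf_header(genome_spec, sample_ids, extra_filters=()) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mutburden-synthetic",
    ]
    for chrom, length in genome_spec:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    for fid, desc in extra_filters:
        lines.append(f'##FILTER=<ID={fid},Description="{desc}">')
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    return "\n".join(lines) + "\n"


def write_multisample_vcf(calls: pd.DataFrame, sample_ids: Sequence[str],
                          genome_spec, path) -> None:
    """Population-caller output: one row per variant key, GT:DP:AD per
    sample; FILTER is TRANCHE when the site failed recalibration."""
    header = _vcf_header(genome_spec, sample_ids,
                         extra_filters=[("TRANCHE", "Failed recalibration tranche")])
    with open(path, "w") as fh:
        fh.write(header)
        if calls.empty:
            return
        grouped = calls.groupby(["chrom", "pos", "ref", "alt"], sort=True)
        for (chrom, pos, ref, alt), sub in grouped:
            per_sample = {r["sample_id"]: r for _, r in sub.iterrows()}
            tranche_ok = all(bool(r.get("tranche_pass", True))
                             for r in per_sample.values())
            cols = []
            for s in sample_ids:
                if s in per_sample:
                    r = per_sample[s]
                    dp, ad = int(r["depth"]), int(r["alt_depth"])
                    cols.append(f"0/1:{dp}:{dp - ad},{ad}")
                else:
                    cols.append("0/0:.:.")
            fh.write("\t".join([
                chrom, str(int(pos)), ".", ref, alt, ".",
                "PASS" if tranche_ok else "TRANCHE", ".", "GT:DP:AD", *cols,
            ]) + "\n")


def write_pairwise_vcf(calls: pd.DataFrame, sample_id: str, genome_spec, path) -> None:
    """Pairwise (tumour-normal style) caller output for one derived line;
    FILTER PASS encodes the KEEP judgment."""
    header = _vcf_header(genome_spec, [sample_id],
                         extra_filters=[("REJECT", "Rejected by the caller judgment")])
    with open(path, "w") as fh:
        fh.write(header)
        for _, r in calls.sort_values(["chrom", "pos", "ref", "alt"]).iterrows():
            dp, ad = int(r["depth"]), int(r["alt_depth"])
            filt = "PASS" if str(r["judgment"]).upper() == "KEEP" else "REJECT"
            fh.write("\t".join([
                r["chrom"], str(int(r["pos"])), ".", r["ref"], r["alt"], ".",
                filt, ".", "GT:DP:AD", f"0/1:{dp}:{dp - ad},{ad}",
            ]) + "\n")


def read_multisample_vcf(path) -> pd.DataFrame:
    """Read the population-caller VCF back into the per-sample call table
    (one row per non-reference sample at each site)."""
    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for v in vcf:
        tranche = v.FILTER is None  # PASS is exposed as None
        dps = v.format("DP")
        ads = v.format("AD")
        gts = v.gt_types  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        for i, s in enumerate(samples):
            if gts[i] in (1, 3):
                dp = int(dps[i][0])
                ad = int(ads[i][1])
                rows.append({"sample_id": s, "chrom": v.CHROM, "pos": v.POS,
                             "ref": v.REF, "alt": v.ALT[0], "depth": dp,
                             "alt_depth": ad, "tranche_pass": tranche})
    vcf.close()
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                                       "depth", "alt_depth", "tranche_pass"])


def read_pairwise_vcf(path) -> pd.DataFrame:
    vcf = VCF(str(path))
    rows = []
    for v in vcf:
        dp = int(v.format("DP")[0][0])
        ad = int(v.format("AD")[0][1])
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
                     "alt": v.ALT[0], "depth": dp, "alt_depth": ad,
                     "judgment": "KEEP" if v.FILTER is None else "REJECT"})
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth",
                                       "alt_depth", "judgment"])


def write_traces_tsv(traces: Sequence[TraceWindow], path) -> None:
    rows = []
    for tr in traces:
        for j, p in enumerate(range(-N_FLANK, N_FLANK + 1)):
            rows.append({"variant_id": tr.variant_id, "position": p,
                         **{ch: tr.amplitudes[k, j] for k, ch in enumerate(CHANNELS)}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path) -> list[TraceWindow]:
    from .traces import traces_from_frame
    return traces_from_frame(pd.read_csv(path, sep="\t"))


def write_sv_tables(sv_calls, sv_support, path_calls, path_support) -> None:
    call_rows = [{
        "sample_id": c.sample_id, "chrom": c.chrom, "start": c.start,
        "end": c.end, "size": c.size, "svtype": c.svtype,
        "algorithm": c.algorithm, "call_id": c.call_id,
    } for c in sv_calls]
    pd.DataFrame(call_rows, columns=["sample_id", "chrom", "start", "end",
                                     "size", "svtype", "algorithm", "call_id"]
                 ).to_csv(path_calls, sep="\t", index=False)
    sup_rows = [{"sv_id": sv_id, "sample_id": s, "molecules": n}
                for sv_id, per in sv_support.items()
                for s, n in sorted(per.items())]
    pd.DataFrame(sup_rows, columns=["sv_id", "sample_id", "molecules"]
                 ).to_csv(path_support, sep="\t", index=False)


def read_sv_tables(path_calls, path_support):
    from .svcompare import SVCall
    calls_df = pd.read_csv(path_calls, sep="\t")
    sup_df = pd.read_csv(path_support, sep="\t")
    support: dict[str, dict[str, int]] = {}
    for _, r in sup_df.iterrows():
        support.setdefault(r["sv_id"], {})[r["sample_id"]] = int(r["molecules"])
    calls = []
    for _, r in calls_df.iterrows():
        sv_id = str(r["call_id"]).split(":")[0]
        calls.append(SVCall(
            sample_id=r["sample_id"], chrom=r["chrom"], start=int(r["start"]),
            end=int(r["end"]), size=int(r["size"]), svtype=r["svtype"],
            algorithm=r["algorithm"], call_id=r["call_id"],
            molecule_support=support.get(sv_id),
        ))
    return calls, support


def write_cohort(dataset: CohortDataset, outdir) -> dict:
    """Serialize a cohort to plain-text files tied together by a YAML
    manifest; returns the manifest dictionary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    genome = list(cfg.genome_spec)

    write_multisample_vcf(
        dataset.hc_calls,
        [dataset.parental_sample_id] + dataset.line_sample_ids,
        genome, out / "hc.vcf",
    )
    mutect_files = {}
    for s, df in dataset.mutect_calls.items():
        fname = f"mutect_{s}.vcf"
        write_pairwise_vcf(df, s, genome, out / fname)
        mutect_files[s] = fname

    (out / "tracks").mkdir(exist_ok=True)
    track_files = {}
    for cat, idx in dataset.annotation_tracks.items():
        fname = f"tracks/{cat}.bed"
        write_bed(list(idx), out / fname)
        track_files[cat] = fname

    known_rows = sorted(dataset.known_variants)
    pd.DataFrame(known_rows, columns=["chrom", "pos", "ref", "alt"]
                 ).to_csv(out / "known_variants.tsv", sep="\t", index=False)
    dataset.predictor_table.to_csv(out / "predictors.tsv", sep="\t", index=False)
    dataset.truth_variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    dataset.integration_pairs.to_csv(out / "integration_pairs.tsv", sep="\t", index=False)
    dataset.integration_truth.to_csv(out / "integration_truth.tsv", sep="\t", index=False)
    write_sv_tables(dataset.sv_calls, dataset.sv_support,
                    out / "sv_calls.tsv", out / "sv_support.tsv")
    write_traces_tsv(dataset.traces, out / "traces.tsv")
    dataset.trace_truth.to_csv(out / "trace_truth.tsv", sep="\t", index=False)

    pwm_payload = {
        pid: {"motif_id": p.motif_id, "scores": p.scores.tolist()}
        for pid, p in dataset.pwms.items()
    }
    with open(out / "pwms.json", "w") as fh:
        json.dump(pwm_payload, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": cfg.seed,
        "genome_spec": [[c, int(l)] for c, l in genome],
        "parental_sample_id": dataset.parental_sample_id,
        "line_sample_ids": list(dataset.line_sample_ids),
        "method_of": dict(dataset.method_of),
        "sv_samples": list(dataset.sv_samples),
        "files": {
            "hc_vcf": "hc.vcf",
            "mutect_vcfs": mutect_files,
            "tracks": track_files,
            "known_variants": "known_variants.tsv",
            "predictors": "predictors.tsv",
            "truth_variants": "truth_variants.tsv",
            "integration_pairs": "integration_pairs.tsv",
            "integration_truth": "integration_truth.tsv",
            "sv_calls": "sv_calls.tsv",
            "sv_support": "sv_support.tsv",
            "traces": "traces.tsv",
            "trace_truth": "trace_truth.tsv",
            "pwms": "pwms.json",
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def load_manifest(cohort_dir) -> dict:
    with open(Path(cohort_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)
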