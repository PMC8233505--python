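"""End-to-end orchestration: simulate -> call -> downstream statistics.

Each stage reads and writes plain files (TSV/FASTA/GFF3/BED) so every stage
is also runnable standalone; rerunning with the same configuration and seed
reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import genome_io
from .caller import CallerParams, calls_to_frame, call_accession
from .context import PermutationParams, distance_distribution
from .chromatin import fold_enrichment
from .expression import de_enrichment_table, gene_cns_delta
from .simulate import (
    AccessionBundle,
    ReferenceBundle,
    SynthConfig,
    derive_accession,
    generate_expression_labels,
    generate_peaks,
    generate_reference,
    planted_gene_deltas,
    write_accession,
    write_reference,
)
from .stats import expected_distinct, shared_event_fraction, variation_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "call", "stats", "context", "atac", "expr", "report"]
    )
    synth: SynthConfig = field(default_factory=SynthConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    perm: PermutationParams = field(default_factory=PermutationParams)

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth = raw.get("synth", {})
        for key in ("cns_len_range", "repeat_len_range", "peak_len_range"):
            if key in synth:
                synth[key] = tuple(synth[key])
        return cls(
            outdir=raw.get("outdir", "cnsvar_run"),
            stages=raw.get("stages", cls.__dataclass_fields__["stages"].default_factory()),
            synth=SynthConfig(**synth),
            caller=CallerParams(**raw.get("caller", {})),
            perm=PermutationParams(**raw.get("perm", {})),
        )


def _log_stage(report: list[dict], name: str, t0: float, **params) -> None:
    entry = {"stage": name, "seconds": round(time.time() - t0, 3), **params}
    logger.info("stage %s done in %.2fs %s", name, entry["seconds"], params)
    report.append(entry)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


def run_pipeline(config: RunConfig) -> str:
    """Execute the requested stages in dependency order; returns the report dir."""
    os.makedirs(config.outdir, exist_ok=True)
    report: list[dict] = []
    ref: ReferenceBundle | None = None
    accessions: list[AccessionBundle] = []

    if "simulate" in config.stages:
        t0 = time.time()
        ref = generate_reference(config.synth)
        ref_dir = os.path.join(config.outdir, "reference")
        write_reference(ref, ref_dir)
        for i in range(config.synth.n_accessions):
            acc = derive_accession(ref, config.synth, i)
            accessions.append(acc)
            acc_dir = os.path.join(config.outdir, acc.name)
            write_accession(acc, acc_dir)
            peaks = generate_peaks(acc, config.synth)
            genome_io.write_bed(peaks, os.path.join(acc_dir, "peaks.bed"))
            deltas = planted_gene_deltas(ref, acc)
            labels = generate_expression_labels(deltas, config.synth, stream=i)
            genome_io.write_tsv(labels, os.path.join(acc_dir, "de_labels.tsv"))
        _log_stage(
            report, "simulate", t0,
            seed=config.synth.seed,
            genome_fa=_hash_file(os.path.join(ref_dir, "genome.fa")),
        )

    calls_frames = []
    if "call" in config.stages:
        if ref is None:
            raise RuntimeError("call stage requires simulate outputs (run simulate first)")
        t0 = time.time()
        records = ref.cns_records()
        summaries = []
        for acc in accessions:
            calls, summary = call_accession(
                records, acc.genome, acc.genes, acc.orthologs, config.caller, acc.name
            )
            frame = calls_to_frame(calls)
            calls_frames.append(frame)
            summaries.append({"accession": acc.name, **summary})
        calls_df = pd.concat(calls_frames, ignore_index=True)
        genome_io.write_tsv(calls_df, os.path.join(config.outdir, "calls.tsv"))
        genome_io.write_tsv(
            pd.DataFrame(summaries), os.path.join(config.outdir, "summary.tsv")
        )
        _log_stage(report, "call", t0, **asdict(config.caller))

    calls_path = os.path.join(config.outdir, "calls.tsv")
    calls_df = genome_io.read_tsv(calls_path) if os.path.exists(calls_path) else None

    if "stats" in config.stages and calls_df is not None:
        t0 = time.time()
        rows = []
        N = len(pd.unique(calls_df["cns_id"]))
        for status in ("pav", "posv"):
            m = variation_matrix(calls_df, status)
            k = m.sum(axis=1).to_numpy()
            observed = int((m.sum(axis=0) >= 1).sum())
            rows.append(
                {
                    "status": status,
                    "universe": N,
                    "observed_distinct": observed,
                    "expected_distinct": round(expected_distinct(k, N), 2),
                    "shared_fraction": (
                        round(shared_event_fraction(m), 4) if observed else np.nan
                    ),
                }
            )
        genome_io.write_tsv(pd.DataFrame(rows), os.path.join(config.outdir, "stats.tsv"))
        _log_stage(report, "stats", t0, universe=N)

    if "context" in config.stages and calls_df is not None and ref is not None:
        t0 = time.time()
        rows = []
        for acc in accessions:
            sub = calls_df[(calls_df["accession"] == acc.name) & (calls_df["status"] != "pav")]
            iv = sub[["chrom", "start", "end", "status"]]
            iv = iv[iv["start"] >= 0]
            dists, _ = distance_distribution(iv, acc.genes, 500)
            for status in ("collinear", "posv"):
                mask = (iv["status"] == status).to_numpy()
                if mask.any():
                    rows.append(
                        {
                            "accession": acc.name,
                            "status": status,
                            "median_abs_gene_distance": float(np.median(np.abs(dists[mask]))),
                            "frac_within_500bp": float(np.mean(np.abs(dists[mask]) <= 500)),
                        }
                    )
        genome_io.write_tsv(pd.DataFrame(rows), os.path.join(config.outdir, "context_stats.tsv"))
        _log_stage(report, "context", t0, n_perm=config.perm.n_perm)

    if "atac" in config.stages and calls_df is not None:
        t0 = time.time()
        rows = []
        for acc in accessions:
            peaks = genome_io.read_bed(os.path.join(config.outdir, acc.name, "peaks.bed"))
            for status in ("collinear", "posv"):
                sub = calls_df[
                    (calls_df["accession"] == acc.name) & (calls_df["status"] == status)
                ][["chrom", "start", "end"]]
                sub = sub[sub["start"] >= 0]
                if not len(sub):
                    continue
                res = fold_enrichment(sub, peaks, acc.chrom_lengths, config.perm, label=status)
                rows.append({"accession": acc.name, **asdict(res)})
        genome_io.write_tsv(pd.DataFrame(rows), os.path.join(config.outdir, "atac_enrichment.tsv"))
        _log_stage(report, "atac", t0, n_perm=config.perm.n_perm)

    if "expr" in config.stages and calls_df is not None and ref is not None:
        t0 = time.time()
        tables = []
        gene_map = ref.cns.set_index("cns_id")["gene_id"]
        for acc in accessions:
            sub = calls_df[calls_df["accession"] == acc.name]
            deltas = gene_cns_delta(sub, gene_map, acc.orthologs)
            labels = genome_io.read_tsv(
                os.path.join(config.outdir, acc.name, "de_labels.tsv")
            )
            up = set(labels.loc[labels["label"] == "up", "gene_id"])
            down = set(labels.loc[labels["label"] == "down", "gene_id"])
            table = de_enrichment_table(deltas, up, down)
            table.insert(0, "accession", acc.name)
            tables.append(table)
        genome_io.write_tsv(
            pd.concat(tables, ignore_index=True), os.path.join(config.outdir, "table1.tsv")
        )
        _log_stage(report, "expr", t0)

    if "report" in config.stages:
        t0 = time.time()
        write_report(config.outdir, calls_df, ref)
        _log_stage(report, "report", t0)

    with open(os.path.join(config.outdir, "run_report.json"), "w") as fh:
        json.dump({"config": _jsonable(config), "stages": report}, fh, indent=2)
    return config.outdir


def _jsonable(config: RunConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=list))


def write_report(outdir: str, calls_df: pd.DataFrame | None, ref=None) -> None:
    """Summary tables and figures: per-accession variant counts sorted by
    PosV (mirrored bar-chart data), CNS length histograms and gene-distance
    summaries per class."""
    if calls_df is None:
        return
    summary = (
        calls_df.groupby("accession")["status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["collinear", "posv", "pav"], fill_value=0)
        .rename(columns=lambda c: f"n_{c}")
        .reset_index()
        .sort_values("n_posv", ascending=False, ignore_index=True)
    )
    genome_io.write_tsv(summary, os.path.join(outdir, "report_accessions.tsv"))
    if ref is not None:
        by_status = calls_df.set_index("cns_id")
        rows = []
        for status in ("collinear", "posv", "pav"):
            ids = by_status.index[by_status["status"] == status]
            if len(ids):
                lens = (
                    ref.cns.set_index("cns_id").loc[pd.unique(ids)].eval("end - start")
                )
                rows.append({"status": status, "n": len(lens), "mean_length": float(lens.mean())})
        genome_io.write_tsv(pd.DataFrame(rows), os.path.join(outdir, "report_lengths.tsv"))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
        x = np.arange(len(summary))
        axes[0].bar(x, summary["n_posv"], color="tab:blue")
        axes[0].set_ylabel("PosV CNS")
        axes[1].bar(x, summary["n_pav"], color="tab:red")
        axes[1].invert_yaxis()
        axes[1].set_ylabel("PAV CNS")
        axes[1].set_xticks(x, summary["accession"], rotation=90, fontsize=6)
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "report_accessions.png"), dpi=100)
        plt.close(fig)
    except Exception:  # plotting is best-effort
        logger.exception("report figure failed")
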