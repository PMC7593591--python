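"""Single-sample pipeline orchestration and reporting.

Runs extraction -> entropy QC -> LCA taxonomic summary -> targeted-
assembly support over one read library, writes all intermediates under
one output prefix, and renders plain-text, TSV, and a self-contained
single-file HTML report (inline SVG, no remote assets).
"""

from __future__ import annotations

import hashlib
import html
import json
import logging
import sys
import tarfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from ssuflash import config, qc_entropy
from ssuflash.assembly_support import assembly_params
from ssuflash.compare import distance_matrix  # noqa: F401  (re-export for reports)
from ssuflash.extract import (
    ReadPair,
    alignment_histograms,
    build_ref_index,
    extract_reads,
    write_fastq_pairs,
    write_sam,
)
from ssuflash.refdb import ReferenceRecord
from ssuflash.taxprofile import (
    classify_pairs,
    render_label,
    summarize,
    write_profile_json,
    write_profile_tsv,
)

logger = logging.getLogger("ssuflash")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class RunReport:
    """Everything a run computed, assembled from stage outputs only."""

    sample_id: str
    parameters: dict
    input_pairs: int = 0
    extracted_pairs: int = 0
    classified_pairs: int = 0
    identity_histogram: pd.Series | None = None
    insert_histogram: pd.Series | None = None
    profile: object | None = None
    entropy_summary: dict | None = None
    assembly_parameters: dict | None = None
    assembled_fraction: float | None = None
    closest_hits: list[dict] = field(default_factory=list)
    stage_failures: list[str] = field(default_factory=list)
    timestamps: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.stage_failures


def run_pipeline(
    pairs: Sequence[ReadPair],
    references: Sequence[ReferenceRecord],
    cfg: config.RunConfig,
) -> RunReport:
    """Execute extract -> entropy -> profile -> assembly-support.

    All intermediates are written under ``cfg.out_prefix``; a stage
    failure is recorded in the report (callers exit non-zero on
    ``report.ok == False``) and later stages that depend on it are
    skipped.
    """
    out = Path(cfg.out_prefix)
    out.parent.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        sample_id=cfg.sample_id,
        parameters={**config.defaults(), "min_identity": cfg.min_identity,
                    "tax_level": cfg.tax_level, "seed": cfg.seed},
        input_pairs=len(pairs),
    )
    report.timestamps["start"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    hits: list = []
    retained: list[ReadPair] = []
    try:
        t0 = time.perf_counter()
        if pairs:
            index = build_ref_index(references)
            hits, retained = extract_reads(pairs, index,
                                           min_identity=cfg.min_identity)
        report.extracted_pairs = len(retained)
        ident, ins = alignment_histograms(hits, min_identity=cfg.min_identity)
        report.identity_histogram = ident
        report.insert_histogram = ins
        ident.to_csv(f"{cfg.out_prefix}.idhistogram.tsv", sep="\t")
        ins.to_csv(f"{cfg.out_prefix}.inserthistogram.tsv", sep="\t")
        if retained:
            write_sam(hits, retained, references, f"{cfg.out_prefix}.sam")
            write_fastq_pairs(retained, f"{cfg.out_prefix}.R1.fq",
                              f"{cfg.out_prefix}.R2.fq")
        logger.info("extract: %d/%d pairs retained (%.1fs)",
                    len(retained), len(pairs), time.perf_counter() - t0)
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("extract stage failed: %s", exc)
        report.stage_failures.append(f"extract: {exc}")

    try:
        if retained:
            stats = [qc_entropy.compute_entropy(s, k=cfg.entropy_k, read_id=p.read_id)
                     for p in retained for s in (p.seq1, p.seq2)
                     if len(s) >= cfg.entropy_k]
            summary = qc_entropy.redundancy_summary(stats)
            report.entropy_summary = {k: v for k, v in summary.items()
                                      if k != "histogram"}
            qc_entropy.write_entropy_tsv(stats, f"{cfg.out_prefix}.entropy.tsv")
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("entropy stage failed: %s", exc)
        report.stage_failures.append(f"entropy: {exc}")

    try:
        assignments = classify_pairs(hits)
        profile = summarize(assignments, level=cfg.tax_level,
                            sample_id=cfg.sample_id)
        report.profile = profile
        report.classified_pairs = profile.total
        write_profile_tsv(profile, f"{cfg.out_prefix}.profile.tsv")
        write_profile_json(profile, f"{cfg.out_prefix}.profile.json")
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("profile stage failed: %s", exc)
        report.stage_failures.append(f"profile: {exc}")

    try:
        if pairs:
            read_len = len(pairs[0].seq1)
            observed = None
            if report.insert_histogram is not None and len(report.insert_histogram):
                h = report.insert_histogram
                observed = float((h.index * h).sum() / h.sum())
            params = assembly_params(read_len, observed)
            report.assembly_parameters = json.loads(params.to_json())
            Path(f"{cfg.out_prefix}.assemblyparams.json").write_text(
                params.to_json())
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("assembly-support stage failed: %s", exc)
        report.stage_failures.append(f"assembly_support: {exc}")

    report.timestamps["end"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_text_report(report, f"{cfg.out_prefix}.report.txt")
    Path(f"{cfg.out_prefix}.report.json").write_text(
        json.dumps(_report_payload(report), indent=1, default=str))
    if cfg.html:
        Path(f"{cfg.out_prefix}.report.html").write_text(render_html(report))
    if cfg.zip_archive:
        archive_results(cfg.out_prefix)
    return report


def _report_payload(report: RunReport) -> dict:
    payload = {
        "sample_id": report.sample_id,
        "input_pairs": report.input_pairs,
        "extracted_pairs": report.extracted_pairs,
        "classified_pairs": report.classified_pairs,
        "entropy_summary": report.entropy_summary,
        "assembly_parameters": report.assembly_parameters,
        "assembled_fraction": report.assembled_fraction,
        "stage_failures": report.stage_failures,
        "parameters": report.parameters,
        "timestamps": report.timestamps,
    }
    if report.profile is not None:
        payload["profile"] = {
            render_label(k, report.profile.level): v
            for k, v in sorted(report.profile.counts.items())
        }
    return payload


def _write_text_report(report: RunReport, path: str) -> None:
    lines = [
        f"sample: {report.sample_id}",
        f"input read pairs: {report.input_pairs}",
        f"extracted read pairs: {report.extracted_pairs}",
        f"classified read pairs: {report.classified_pairs}",
    ]
    if report.entropy_summary:
        lines.append(f"mean redundancy R: {report.entropy_summary['mean_R']:.4f}")
    if report.profile is not None and report.profile.total:
        lines.append("taxonomic summary:")
        for tax, n in sorted(report.profile.counts.items(),
                             key=lambda kv: -kv[1]):
            pct = 100.0 * n / report.profile.total
            lines.append(f"  {render_label(tax, report.profile.level)}"
                         f"\t{n}\t{pct:.1f}%")
    if report.assembly_parameters:
        lines.append(f"assembly parameters: {report.assembly_parameters}")
    for fail in report.stage_failures:
        lines.append(f"STAGE FAILURE: {fail}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# HTML report
# --------------------------------------------------------------------------

def _svg_barplot(items: list[tuple[str, float]], width: int = 640) -> str:
    """Minimal inline SVG horizontal barplot (percent scale)."""
    if not items:
        return ""
    bar_h, gap, label_w = 18, 6, 260
    height = len(items) * (bar_h + gap) + gap
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}" font-family="sans-serif" font-size="12">']
    scale = (width - label_w - 60) / 100.0
    for i, (label, pct) in enumerate(items):
        y = gap + i * (bar_h + gap)
        parts.append(
            f'<text x="{label_w - 6}" y="{y + bar_h - 5}" text-anchor="end">'
            f"{html.escape(label)}</text>")
        parts.append(
            f'<rect x="{label_w}" y="{y}" width="{max(1.0, pct * scale):.1f}" '
            f'height="{bar_h}" fill="#4878a8"/>')
        parts.append(
            f'<text x="{label_w + pct * scale + 4:.1f}" y="{y + bar_h - 5}">'
            f"{pct:.1f}%</text>")
    parts.append("</svg>")
    return "".join(parts)


def render_html(report: RunReport) -> str:
    """Self-contained single-file HTML report (inline SVG, no remote assets).

    Every number shown is taken from the same report object that
    produced the TSV outputs, so the two always agree.
    """
    rows = []
    if report.profile is not None and report.profile.total:
        for tax, n in sorted(report.profile.counts.items(), key=lambda kv: -kv[1]):
            pct = 100.0 * n / report.profile.total
            rows.append((render_label(tax, report.profile.level), n, pct))
    banner = ""
    if not rows:
        banner = '<p class="banner"><strong>no SSU detected</strong></p>'
    failures = "".join(
        f'<p class="fail">STAGE FAILURE: {html.escape(f)}</p>'
        for f in report.stage_failures)
    table = "".join(
        f"<tr><td>{html.escape(t)}</td><td>{n}</td><td>{pct:.1f}</td></tr>"
        for t, n, pct in rows)
    entropy = ""
    if report.entropy_summary:
        entropy = (f"<p>mean informational redundancy R = "
                   f"{report.entropy_summary['mean_R']:.4f} "
                   f"(n = {report.entropy_summary['n']})</p>")
    params = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in sorted(report.parameters.items()))
    svg = _svg_barplot([(t, pct) for t, _n, pct in rows[:25]])
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>ssuflash: {html.escape(report.sample_id)}</title>
<style>
body{{font-family:sans-serif;margin:2em;max-width:60em}}
table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:2px 8px}}
.banner{{background:#fee;padding:1em}}.fail{{color:#a00}}
</style></head><body>
<h1>SSU rRNA profile: {html.escape(report.sample_id)}</h1>
{failures}{banner}
<p>input read pairs: {report.input_pairs} &middot;
extracted: {report.extracted_pairs} &middot;
classified: {report.classified_pairs}</p>
{entropy}
<h2>Taxonomic summary</h2>
{svg}
<table><tr><th>taxon</th><th>pairs</th><th>%</th></tr>{table}</table>
<h2>Parameters</h2>
<table>{params}</table>
<p><small>generated {html.escape(report.timestamps.get('end', ''))}</small></p>
</body></html>
"""


# --------------------------------------------------------------------------
# Archiving
# --------------------------------------------------------------------------

def archive_results(prefix: str) -> Path:
    """tar+gzip all outputs under ``prefix`` with a checksum manifest."""
    prefix_path = Path(prefix)
    files = sorted(p for p in prefix_path.parent.glob(prefix_path.name + ".*")
                   if p.suffix not in (".gz",))
    manifest = {}
    for p in files:
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest_path = Path(f"{prefix}.manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    archive = Path(f"{prefix}.tar.gz")
    with tarfile.open(archive, "w:gz") as tar:
        tar.add(manifest_path, arcname=manifest_path.name)
        for p in files:
            tar.add(p, arcname=p.name)
    return archive
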