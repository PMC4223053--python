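"""End-to-end orchestration of the curation and characterization stages.

Stage order is fixed: read trimming (when reads are given) -> greedy
clustering -> chimera splitting -> containment purge -> length filter ->
assembly statistics -> annotation -> k-mer spectrum.  Assembly itself is
external and consumed as a contig FASTA.  Every artifact is written under
the output directory with a sha256 manifest, so byte-identity of reruns is
checkable; contig counts are reconciled across consecutive stages when the
report is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import annotation, io, kmers, readqc
from .curation import (
    CurationConfig,
    apply_split_decisions,
    assembly_stats,
    detect_chimeras,
    greedy_cluster,
    length_filter,
    purge_contained,
)

logger = logging.getLogger("transcurate")

__all__ = ["RunConfig", "StageRecord", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated inputs, thresholds and stage toggles for one run."""

    contigs: str
    outdir: str
    reads: Optional[str] = None
    protein_hits: Optional[str] = None
    nuc_hits: Optional[str] = None
    core_ids: Optional[str] = None
    go_annotations: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    # stage toggles
    do_trim: bool = True
    do_cluster: bool = True
    do_split: bool = True
    do_purge: bool = True
    do_length_filter: bool = True
    do_annotation: bool = True
    do_kmer: bool = True
    # thresholds
    trim_prefix: int = 14
    quality_floor: int = 20
    min_read_length: int = 50
    max_ambiguous: int = 2
    chimera_evalue_max: float = 1e-20
    chimera_min_gap: int = 100
    purge_min_identity: float = 0.90
    purge_min_coverage: float = 0.50
    cluster_identity: float = 0.90
    min_contig_length: int = 200
    kmer_k: int = 21
    kmer_canonical: bool = False
    completeness_evalue_max: float = 1e-15
    go_min_genes: int = 20

    def curation_config(self) -> CurationConfig:
        return CurationConfig(
            chimera_evalue_max=self.chimera_evalue_max,
            chimera_min_gap=self.chimera_min_gap,
            purge_min_identity=self.purge_min_identity,
            purge_min_coverage=self.purge_min_coverage,
            cluster_identity=self.cluster_identity,
            min_contig_length=self.min_contig_length,
        )

    def trim_policy(self) -> readqc.TrimPolicy:
        return readqc.TrimPolicy(
            fixed_prefix=self.trim_prefix,
            quality_floor=self.quality_floor,
            min_length=self.min_read_length,
            max_ambiguous=self.max_ambiguous,
        )


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    elapsed_s: float
    details: dict = field(default_factory=dict)


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    stats_before: Optional[dict] = None
    stats_after: Optional[dict] = None
    completeness: Optional[dict] = None
    warnings: list[str] = field(default_factory=list)

    def reconcile(self) -> None:
        """Contig-count chain check: out of stage i == in of stage i+1."""
        chain = [s for s in self.stages if s.details.get("unit") == "contigs"]
        for prev, nxt in zip(chain, chain[1:]):
            if prev.n_out != nxt.n_in:
                raise AssertionError(
                    f"count mismatch: {prev.stage} out {prev.n_out} != "
                    f"{nxt.stage} in {nxt.n_in}"
                )

    def to_dict(self) -> dict:
        return {
            "stages": [asdict(s) for s in self.stages],
            "stats_before": self.stats_before,
            "stats_after": self.stats_after,
            "completeness": self.completeness,
            "warnings": self.warnings,
        }


_DOMAINS = {
    "purge_min_identity": (0.0, 1.0),
    "purge_min_coverage": (0.0, 1.0),
    "cluster_identity": (0.0, 1.0),
}
_PATH_FIELDS = ("contigs", "reads", "protein_hits", "nuc_hits", "core_ids",
                "go_annotations")


def validate_config(path: str | Path) -> tuple[Optional[RunConfig], list[str]]:
    """Parse and validate a YAML run config, reporting every violation at once."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except Exception as exc:  # unparseable file -> single parse error
        return None, [f"parse error: {exc}"]
    if not isinstance(raw, dict):
        return None, ["parse error: config must be a mapping"]

    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    for key in sorted(unknown):
        errors.append(f"unknown field: {key}")
    if "contigs" not in raw:
        errors.append("missing required field: contigs")
    if "outdir" not in raw:
        errors.append("missing required field: outdir")
    for name, (lo, hi) in _DOMAINS.items():
        if name in raw and not (lo < float(raw[name]) <= hi):
            errors.append(f"{name}={raw[name]} outside ({lo}, {hi}]")
    for name in ("min_contig_length", "chimera_min_gap", "kmer_k"):
        if name in raw and int(raw[name]) <= 0:
            errors.append(f"{name} must be positive")
    for name in _PATH_FIELDS:
        value = raw.get(name)
        if value is not None and not Path(value).exists():
            errors.append(f"{name}: no such file {value}")
    if errors:
        return None, errors
    return RunConfig(**{k: v for k, v in raw.items() if k in known}), []


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured stages in order and write all artifacts.

    Rerunning with the same config and inputs is byte-identical (the
    manifest records a sha256 per artifact).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    artifacts: list[Path] = []

    def record(stage: str, n_in: int, n_out: int, t0: float, **details) -> None:
        rec = StageRecord(stage, n_in, n_out, round(time.time() - t0, 3), details)
        report.stages.append(rec)
        logger.info("stage=%s n_in=%d n_out=%d elapsed=%.3fs",
                    stage, n_in, n_out, rec.elapsed_s)

    # --- read trimming
    if cfg.do_trim and cfg.reads:
        t0 = time.time()
        raw_reads = [
            readqc.ReadRecord(rid, seq, tuple(quals))
            for rid, seq, quals in io.read_fastq(cfg.reads)
        ]
        kept, summary = readqc.process_reads(raw_reads, cfg.trim_policy())
        path = outdir / "reads.trimmed.fastq"
        io.write_fastq(
            ((r.read_id, r.sequence, list(r.qualities)) for r in kept), path
        )
        artifacts.append(path)
        path = outdir / "trim_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        artifacts.append(path)
        record("trim", summary["n_in"], summary["n_kept"], t0, unit="reads")

    contigs = io.read_fasta(cfg.contigs)
    report.stats_before = asdict(assembly_stats(contigs))
    ccfg = cfg.curation_config()

    # --- greedy clustering (representatives survive)
    if cfg.do_cluster:
        t0 = time.time()
        clusters = greedy_cluster(contigs, ccfg.cluster_identity, ccfg.kmer_seed_size)
        reps = {cl.representative_id for cl in clusters}
        n_in = len(contigs)
        contigs = [c for c in contigs if c.contig_id in reps]
        with open(outdir / "clusters.tsv", "w") as fh:
            for cl in clusters:
                fh.write(f"{cl.representative_id}\t{','.join(cl.member_ids)}\n")
        artifacts.append(outdir / "clusters.tsv")
        record("cluster", n_in, len(contigs), t0, unit="contigs",
               n_clusters=len(clusters))

    # --- chimera detection / splitting
    if cfg.do_split and cfg.protein_hits:
        t0 = time.time()
        hits = io.read_hits(cfg.protein_hits)
        hits = hits[hits["qseqid"].isin({c.contig_id for c in contigs})]
        decisions = detect_chimeras(hits, contigs, ccfg)
        n_in = len(contigs)
        contigs, pieces = apply_split_decisions(contigs, decisions)
        with open(outdir / "split_log.tsv", "w") as fh:
            for d in decisions:
                if d.status != "keep":
                    fh.write(
                        f"{d.contig_id}\t{d.status}\t{d.breakpoint if d.breakpoint is not None else ''}"
                        f"\t{d.left_protein or ''}\t{d.right_protein or ''}\n"
                    )
        artifacts.append(outdir / "split_log.tsv")
        record("split", n_in, len(contigs), t0, unit="contigs",
               n_split=len(pieces) // 2,
               n_manual_review=sum(d.status == "manual_review" for d in decisions))

    # --- containment purge
    if cfg.do_purge:
        t0 = time.time()
        nuc = io.read_hits(cfg.nuc_hits) if cfg.nuc_hits else None
        n_in = len(contigs)
        contigs, purge_log = purge_contained(contigs, ccfg, nuc_hits=nuc)
        with open(outdir / "purge_log.tsv", "w") as fh:
            for row in purge_log:
                fh.write(
                    f"{row['purged_id']}\t{row['kept_id']}\t"
                    f"{row['pct_identity']:.2f}\t{row['coverage']:.3f}\n"
                )
        artifacts.append(outdir / "purge_log.tsv")
        record("purge", n_in, len(contigs), t0, unit="contigs",
               n_purged=len(purge_log))

    # --- length filter
    if cfg.do_length_filter:
        t0 = time.time()
        n_in = len(contigs)
        contigs = length_filter(contigs, ccfg.min_contig_length)
        record("length_filter", n_in, len(contigs), t0, unit="contigs")

    curated_path = outdir / "contigs.curated.fasta"
    io.write_fasta(contigs, curated_path)
    artifacts.append(curated_path)
    report.stats_after = asdict(assembly_stats(contigs))

    # --- annotation
    if cfg.do_annotation and cfg.protein_hits:
        t0 = time.time()
        hits = io.read_hits(cfg.protein_hits)
        hits = hits[hits["qseqid"].isin({c.contig_id for c in contigs})]
        best = annotation.best_hits(hits, "reference")
        orf_stats = [annotation.longest_orf(c) for c in contigs]
        flags = {c.contig_id: c.contig_id in best.per_contig for c in contigs}
        orf_summary = annotation.orf_fraction_summary(orf_stats, flags)
        out = {
            "n_contigs_matched": best.n_contigs_matched,
            "n_subjects_hit": len(best.subjects),
            "orf_summary": asdict(orf_summary),
        }
        if cfg.core_ids:
            core = {
                line.strip() for line in open(cfg.core_ids) if line.strip()
            }
            rep = annotation.completeness(hits, core, cfg.completeness_evalue_max)
            report.completeness = asdict(rep)
            out["completeness"] = asdict(rep)
        if cfg.go_annotations:
            ann = io.read_go_annotations(cfg.go_annotations)
            matched = {h.subject_id for h in best.per_contig.values()}
            rows, summary = annotation.go_conservation(matched, ann, cfg.go_min_genes)
            out["go_summary"] = {"n_matched": summary[0], "n_annotated": summary[1]}
            with open(outdir / "go_conservation.tsv", "w") as fh:
                for r in rows:
                    fh.write(
                        f"{r.term_id}\t{r.term_name}\t{r.namespace}\t"
                        f"{r.n_genes}\t{r.n_matched}\t{r.proportion:.4f}\n"
                    )
            artifacts.append(outdir / "go_conservation.tsv")
        path = outdir / "annotation.json"
        path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
        artifacts.append(path)
        record("annotation", len(contigs), len(contigs), t0, unit="contigs")

    # --- k-mer spectrum
    if cfg.do_kmer:
        t0 = time.time()
        spectrum = kmers.count_kmers(contigs, cfg.kmer_k, cfg.kmer_canonical)
        tbl = kmers.frequency_spectrum(spectrum)
        path = outdir / "kmer_spectrum.tsv"
        tbl.to_csv(path, sep="\t", index=False)
        artifacts.append(path)
        record("kmer", len(contigs), len(contigs), t0, unit="contigs",
               total_kmers=spectrum.total_kmers,
               distinct_kmers=spectrum.distinct_kmers)

    report.reconcile()
    manifest = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return report
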