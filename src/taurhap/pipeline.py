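"""End-to-end orchestration: simulate → map → consensus → type → report.

The pipeline mirrors an aDNA mitogenome workflow: per specimen it maps reads
to the circular reference, applies the mapping-quality/mismatch/gap filters,
removes coordinate duplicates, builds a pileup, calls a 75%-threshold
consensus, profiles damage, and types the mitochondrial haplogroup; the
cohort stage collapses control-region haplotypes, builds a median-joining
network and writes diversity and haplogroup-frequency tables.  All
randomness derives from a single seed, so rerunning a configuration
reproduces every machine output byte for byte (timestamps only appear in
the human-readable log).  Failure of one specimen is recorded and does not
abort the others.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._util import derive_seed
from .align import build_pileup, deduplicate, filter_alignments, map_reads, write_sam
from .consensus import call_consensus
from .damage import authenticity_check, misincorporation_profile
from .diversity import haplogroup_frequencies, summarize
from .haplotypes import assign_mt_haplogroup
from .network import collapse_haplotypes, median_joining, write_edgelist, write_graphml
from .panels import PanelConfigError, default_panel_path, load_panels
from .reference import ReferenceGenome
from .simulate import (DamageParams, CohortRow, CohortSpec, colonial_cohort_spec,
                       make_cohort, make_reference, read_fasta, write_fasta,
                       write_fastq, write_manifest, write_truth_sam,
                       DEFAULT_REFERENCE_LENGTH, DEFAULT_GC, dloop_region)


class ConfigError(ValueError):
    """Invalid configuration; distinct from runtime processing failures."""


@dataclass
class PipelineConfig:
    outdir: str = "taurhap_run"
    seed: int = 1
    reference_fasta: str | None = None        # None -> synthetic reference
    reference_length: int = DEFAULT_REFERENCE_LENGTH
    gc: float = DEFAULT_GC
    panel_path: str | None = None             # None -> shipped default panels
    cohort_tsv: str | None = None             # None -> colonial default roster
    coverage: float = 30.0
    overhang_p: float = 0.3
    delta_ss: float = 0.4
    delta_ds: float = 0.02
    frag_mean: float = 70.0
    frag_sd: float = 0.3
    seq_error: float = 0.001
    k: int = 13
    min_mapq: int = 30
    max_mismatch_frac: float = 0.05
    max_gap_frac: float = 0.05
    consensus_threshold: float = 0.75
    min_depth: int = 3
    dloop_start: int | None = None            # None -> last 700 bases
    dloop_end: int | None = None
    epsilon: int = 0
    write_sam_files: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not 0.5 < self.consensus_threshold <= 1.0:
            raise ConfigError("consensus_threshold must be in (0.5, 1]")
        for name in ("max_mismatch_frac", "max_gap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")
        if self.min_mapq < 0 or self.min_depth < 0:
            raise ConfigError("min_mapq and min_depth must be >= 0")
        for p in (self.reference_fasta, self.panel_path, self.cohort_tsv):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured file does not exist: {p}")

    def damage_params(self) -> DamageParams:
        return DamageParams(overhang_p=self.overhang_p, delta_ss=self.delta_ss,
                            delta_ds=self.delta_ds, frag_mean=self.frag_mean,
                            frag_sd=self.frag_sd, seq_error=self.seq_error,
                            coverage=self.coverage)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("outdir")      # output location does not change the science
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _load_cohort_tsv(path: str) -> CohortSpec:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    required = {"specimen_id", "haplogroup"}
    if not required <= set(df.columns):
        raise ConfigError(f"cohort TSV must have columns {sorted(required)}")
    rows = []
    for _idx, r in df.iterrows():
        rows.append(CohortRow(str(r["specimen_id"]), str(r["haplogroup"]),
                              int(r.get("n_private", 3)), int(r.get("seed", 0))))
    return CohortSpec(tuple(rows))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a summary dict (also written as JSON)."""
    config.validate()
    t0 = time.time()
    out = Path(config.outdir)
    (out / "specimens").mkdir(parents=True, exist_ok=True)
    (out / "cohort").mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    panel_path = config.panel_path or default_panel_path()
    panels = load_panels(panel_path)
    log(f"loaded {len(panels.names())} panels from {panel_path}")

    if config.reference_fasta:
        recs = read_fasta(config.reference_fasta)
        name, seq = next(iter(recs.items()))
        ref = ReferenceGenome(name, seq, circular=True)
    else:
        ref = make_reference(config.reference_length, config.gc,
                             derive_seed(config.seed, "reference"))
    spec = (_load_cohort_tsv(config.cohort_tsv) if config.cohort_tsv
            else colonial_cohort_spec())
    dloop = ((config.dloop_start, config.dloop_end)
             if config.dloop_start and config.dloop_end
             else dloop_region(len(ref)))

    cohort = make_cohort(spec, ref, panels, config.damage_params(),
                         seed=config.seed, private_region=dloop)
    ref = cohort.reference
    write_fasta({ref.name: ref.sequence}, out / "reference.fasta")
    write_manifest(cohort, out / "cohort" / "manifest.tsv")
    log(f"simulated {len(spec)} specimens on {len(ref)} bp reference")

    calls = []
    verdicts = {}
    consensi = {}
    failures = {}
    stage_counts = {}
    for row in spec:
        sid = row.specimen_id
        try:
            readset = cohort.readsets[sid]
            write_fastq(readset, out / "specimens" / f"{sid}.fastq")
            write_truth_sam(readset, out / "specimens" / f"{sid}.truth.sam")
            mapped = map_reads(readset, ref, k=config.k)
            kept = filter_alignments(
                mapped.alignments, max_mismatch_frac=config.max_mismatch_frac,
                max_gap_frac=config.max_gap_frac, min_mapq=config.min_mapq)
            deduped = deduplicate(kept, ref_length=len(ref))
            if config.write_sam_files:
                write_sam(deduped, ref, out / "specimens" / f"{sid}.mapped.sam")
            pileup = build_pileup(deduped, ref)
            cons = call_consensus(pileup, threshold=config.consensus_threshold,
                                  min_depth=config.min_depth)
            cons.to_fasta(out / "specimens" / f"{sid}.consensus.fasta", name=sid)
            profile = misincorporation_profile(deduped, ref)
            profile.to_tsv(out / "specimens" / f"{sid}.damage.tsv")
            verdicts[sid] = authenticity_check(profile).verdict
            call = assign_mt_haplogroup(cons, ref, panels, specimen_id=sid)
            calls.append(call)
            consensi[sid] = cons
            stage_counts[sid] = {
                "reads": len(readset), "mapped": len(mapped.alignments),
                "unmapped": len(mapped.unmapped), "filtered": len(kept),
                "deduped": len(deduped), "consensus_N": cons.aligned.count("N")}
            log(f"{sid}: {stage_counts[sid]} -> {call.status} "
                f"{call.haplogroup or ''} damage={verdicts[sid]}")
        except Exception as exc:   # isolate per-specimen failures
            failures[sid] = f"{type(exc).__name__}: {exc}"
            log(f"{sid}: FAILED ({failures[sid]})")

    import pandas as pd
    calls_df = pd.DataFrame(
        [(c.specimen_id, c.haplogroup or "", c.status,
          round(c.completeness, 4), verdicts.get(c.specimen_id, ""))
         for c in calls],
        columns=["specimen_id", "mt_haplogroup", "status", "completeness",
                 "damage_verdict"])
    calls_df.to_csv(out / "cohort" / "calls.tsv", sep="\t", index=False)

    freq = haplogroup_frequencies(calls)
    freq.to_tsv(out / "cohort" / "frequencies.tsv")

    summary: dict = {"version": __version__, "config_hash": config.config_hash(),
                     "n_specimens": len(spec), "failures": failures,
                     "stage_counts": stage_counts,
                     "haplogroup_counts": freq.counts}
    if len(consensi) >= 2:
        aligned = {sid: c.aligned for sid, c in consensi.items()}
        table = collapse_haplotypes(aligned, region=dloop)
        table.to_tsv(out / "cohort" / "haplotypes.tsv")
        net = median_joining(table, epsilon=config.epsilon)
        write_graphml(net, out / "cohort" / "network.graphml")
        write_edgelist(net, out / "cohort" / "network_edges.tsv")
        report = summarize(aligned, region=dloop)
        report.to_tsv(out / "cohort" / "diversity.tsv")
        summary["diversity"] = report.rounded()
        summary["n_haplotypes"] = len(table)
    log(f"pipeline finished in {time.time() - t0:.1f}s")

    with open(out / "run_log.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
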