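"""End-to-end pipeline: simulate -> QC -> align -> SNPs -> expression -> stats.

One structured config drives all stages; every stage writes its artifacts
plus a marker stamped with the config hash, so a rerun with an identical
config can resume from cached outputs and a rerun after any parameter
change recomputes.  Sample QC (read count and mean read length) excludes
failing samples from the expression stage only — their reads still
contribute to pileups and SNP calling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import align as alignmod
from . import expression as exprmod
from . import simulate as simmod
from . import stats as statsmod
from . import variants as varmod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters plus the master seed."""

    seed: int = 0
    outdir: str = "run"
    # synthetic data
    n_transcripts: int = 20
    length_mean: float = 500.0
    length_sd: float = 120.0
    cds_fraction: float = 0.5
    gc: float = 0.45
    n_ao: int = 4
    n_lm: int = 3
    reads_per_sample: int | list = 5000  # scalar, or one count per sample
    read_length_mean: float = 187.0
    read_length_sd: float = 60.0
    read_length_min: int = 40
    sub_rate: float = 0.005
    indel_rate: float = 0.002
    n_shared: int = 6
    n_fixed: int = 6
    n_group_poly: int = 6
    n_gap_alleles: int = 1
    poly_frequency: float = 0.5
    n_de: int = 8
    fold_min: float = 2.0
    fold_max: float = 200.0
    weight_sd_log2: float = 1.0  # spread of baseline expression weights
    edge_margin: int = 5  # keep planted variants this far from transcript ends
    # alignment
    k: int = 15
    min_identity: float = 0.90
    mismatch_penalty: int = 20
    match_score: int = 10
    gap_open: int = 20
    gap_extend: int = 5
    max_gap: int = 15
    seed_stride: int = 5
    # SNP calling
    min_depth: int = 10
    min_allele_reads: int = 2
    freq_low: float = 0.25
    freq_high: float = 0.75
    present_min: int = 2
    # QC (expression stage only)
    qc_min_reads: int = 1000
    qc_min_mean_len: int = 100
    # expression
    de_tier: float = 8.0
    de_alpha: float = 0.05
    pseudocount: float = 0.1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_toy_config(outdir: str = "run", seed: int = 0) -> RunConfig:
    """The default small run: 20 transcripts, 7 samples, 5k reads each."""
    return RunConfig(seed=seed, outdir=outdir)


def snp_recovery_config(outdir: str = "run_recovery", seed: int = 1) -> RunConfig:
    """The variant-recovery experiment: can the funnel recover planted
    group-exclusive variants?

    Conditions are chosen so the planted truth is recoverable in principle
    through the 25-75% raw-read window: uniform expression (so per-site
    depth is controlled, ~260x pooled), within-group polymorphism frequency
    0.75 (its pooled alt fraction, frequency x group read share, then sits
    well inside the window for both the 4-sample and the 3-sample group),
    error rates at the low end of the platform's range, no expression
    effects, and variants planted clear of the coverage taper at transcript
    ends.
    """
    return RunConfig(
        seed=seed,
        outdir=outdir,
        n_de=0,
        poly_frequency=0.75,
        n_shared=6,
        n_fixed=10,
        n_group_poly=10,
        n_gap_alleles=2,
        reads_per_sample=2000,
        sub_rate=0.0002,
        indel_rate=0.0001,
        weight_sd_log2=0.0,
        edge_margin=150,
    )


def snp_recovery_metrics(run: "PipelineRun") -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of group-exclusive SNP
    calls against the planted truth, matched by (transcript, position)."""
    truth = {
        (v.transcript_id, v.position)
        for v in run.truth.variants
        if v.var_class != simmod.SHARED_POLYMORPHISM
    }
    called = {(s.transcript_id, s.position) for s in run.snps.group_specific}
    tp = len(truth & called)
    sensitivity = tp / len(truth) if truth else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return sensitivity, fdp


def realized_fold_changes(run: "PipelineRun") -> pd.Series:
    """True LM/AO relative-concentration ratio per transcript.

    Libraries are not normalized, so what the RPKM analysis measures is the
    transcript's share of its library.  Planting a fold change on some
    transcripts renormalizes every other transcript's share (the
    composition effect), so the realized ratio of per-sample weights — not
    the planted multiplier — is the ground truth the test should recover.
    """
    if run.plans is None:
        raise RuntimeError("sample plans unavailable (run reloaded from disk)")
    ids = [t.id for t in run.reference]
    ao = np.mean([p.weights for p in run.plans if p.group == "AO"], axis=0)
    lm = np.mean([p.weights for p in run.plans if p.group == "LM"], axis=0)
    return pd.Series(lm / ao, index=ids)


def de_recovery_metrics(run: "PipelineRun") -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of significant DE calls
    against transcripts whose realized concentration ratio reaches the
    config's fold-change tier."""
    tier = run.config.de_tier
    fc = realized_fold_changes(run)
    truth = {t for t, f in fc.items() if max(f, 1.0 / f) >= tier}
    called = set(run.de.index[run.de["significant"]])
    tp = len(truth & called)
    sensitivity = tp / len(truth) if truth else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return sensitivity, fdp


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    n_reads: int
    mean_length: float
    passed: bool


def qc_samples(
    reads_by_sample: Mapping[str, Sequence],
    min_reads: int = 60_000,
    min_mean_len: float = 150.0,
) -> list[SampleQC]:
    """Per-sample read count and mean length; fail under either threshold.

    Defaults match a 454 study's scale, where a library of 51,697 short
    reads was dropped from the expression analysis; scale them down in
    small simulated runs.
    """
    out = []
    for sid, reads in reads_by_sample.items():
        n = len(reads)
        mean_len = float(np.mean([len(r.sequence) for r in reads])) if n else 0.0
        out.append(
            SampleQC(sid, n, mean_len, passed=n >= min_reads and mean_len >= min_mean_len)
        )
    return out


def qc_fastq(path: str | Path) -> tuple[int, float]:
    """(read count, mean length) recounted directly from a FASTQ file."""
    from Bio import SeqIO

    n = 0
    total = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            total += len(rec.seq)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read FASTQ for sample file {path}: {exc}") from exc
    return n, (total / n if n else 0.0)


# ---------------------------------------------------------------------------
# stages


class PipelineRun:
    """Stateful driver over one run directory."""

    def __init__(self, config: RunConfig, resume: bool = True):
        self.config = config
        self.resume = resume
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.outdir / "config.yaml")
        # in-memory state, populated by stages (or reloaded)
        self.reference: list[simmod.ReferenceTranscript] | None = None
        self.truth: simmod.TruthSet | None = None
        self.plans: list[simmod.SamplePlan] | None = None
        self.reads: dict[str, list[simmod.SimulatedRead]] | None = None
        self.qc: list[SampleQC] | None = None
        self.alignments: list[alignmod.ReadAlignment] | None = None
        self.pileup: alignmod.Pileup | None = None
        self.snps: varmod.SnpCallSet | None = None
        self.expr: exprmod.ExpressionMatrix | None = None
        self.de: pd.DataFrame | None = None
        self.report: statsmod.PipelineReport | None = None

    # -- stage plumbing ----------------------------------------------------
    def _marker(self, stage: str) -> Path:
        return self.outdir / f".{stage}.done"

    def _stamp(self, stage: str) -> None:
        self._marker(stage).write_text(
            json.dumps({"stage": stage, "config_hash": self.config.config_hash, "seed": self.config.seed})
        )

    def _cached(self, stage: str) -> bool:
        m = self._marker(stage)
        if not (self.resume and m.exists()):
            return False
        try:
            return json.loads(m.read_text())["config_hash"] == self.config.config_hash
        except (json.JSONDecodeError, KeyError):
            return False

    @property
    def groups(self) -> dict[str, str]:
        if self.plans is not None:
            return {p.sample_id: p.group for p in self.plans}
        out = {}
        for line in (self.outdir / "manifest.tsv").read_text().splitlines()[1:]:
            sid, group = line.split("\t")
            out[sid] = group
        return out

    def _load_simulate(self) -> bool:
        """Reload cached simulate outputs; True on success."""
        from Bio import SeqIO

        needed = ["reference.fasta", "truth.json", "manifest.tsv"]
        if not all((self.outdir / f).exists() for f in needed):
            return False
        self.reference = simmod.read_fasta(self.outdir / "reference.fasta")
        payload = json.loads((self.outdir / "truth.json").read_text())
        self.truth = simmod.TruthSet(
            variants=[
                simmod.PlantedVariant(
                    v["transcript"], v["pos"], v["ref"], v["alt"], v["class"], v["group"], v["freq"]
                )
                for v in payload["variants"]
            ],
            fold_changes=payload["fold_changes"],
            seed=payload["seed"],
        )
        plans_file = self.outdir / "plans.json"
        if plans_file.exists():
            self.plans = [
                simmod.SamplePlan(
                    sample_id=d["sample_id"],
                    group=d["group"],
                    n_reads=d["n_reads"],
                    weights=np.array(d["weights"]),
                    read_length_mean=d["read_length_mean"],
                    read_length_sd=d["read_length_sd"],
                    read_length_min=d["read_length_min"],
                    sub_rate=d["sub_rate"],
                    indel_rate=d["indel_rate"],
                )
                for d in json.loads(plans_file.read_text())
            ]
        self.reads = {}
        for sid in self.groups:
            fq = self.outdir / "reads" / f"{sid}.fastq"
            if not fq.exists():
                return False
            self.reads[sid] = [
                simmod.SimulatedRead(rec.id, str(rec.seq), "?" * len(rec.seq))
                for rec in SeqIO.parse(str(fq), "fastq")
            ]
        logger.info("simulate stage: reloaded cached outputs")
        return True

    def _load_align(self) -> bool:
        """Reload cached alignments from SAM; True on success."""
        import pysam

        sam = self.outdir / "alignments.sam"
        if not sam.exists() or self.reference is None or self.reads is None:
            return False
        by_id = {t.id: t for t in self.reference}
        code_op = {0: "M", 1: "I", 2: "D", 4: "S", 8: "X"}
        alignments = []
        with pysam.AlignmentFile(str(sam), "r") as fh:
            for seg in fh:
                tid = seg.reference_name
                tseq = by_id[tid].sequence
                ops: list[tuple[str, int]] = []
                i, j = 0, seg.reference_start
                matches = columns = 0
                for code, n in seg.cigartuples:
                    op = code_op[code]
                    if op == "M":  # re-split into match/mismatch vs reference
                        for _ in range(n):
                            same = seg.query_sequence[i] == tseq[j]
                            matches += same
                            columns += 1
                            sym = "M" if same else "X"
                            if ops and ops[-1][0] == sym:
                                ops[-1] = (sym, ops[-1][1] + 1)
                            else:
                                ops.append((sym, 1))
                            i += 1
                            j += 1
                    else:
                        if op == "I":
                            i += n
                        elif op == "D":
                            j += n
                        elif op == "S":
                            i += n
                        if op in "ID":
                            columns += n
                        ops.append((op, n))
                alignments.append(
                    alignmod.ReadAlignment(
                        read_id=seg.query_name,
                        sample_id=seg.get_tag("RG"),
                        transcript_id=tid,
                        start=seg.reference_start,
                        strand="-" if seg.is_reverse else "+",
                        ops=tuple(ops),
                        identity=matches / columns if columns else 0.0,
                        score=int(seg.get_tag("AS")),
                        query=seg.query_sequence,
                    )
                )
        self.alignments = alignments
        self.pileup = alignmod.build_pileup(alignments, self.reference, list(self.reads.keys()))
        logger.info("align stage: reloaded %d cached alignments", len(alignments))
        return True

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        if self._cached("simulate") and self._load_simulate():
            return
        cfg = self.config
        logger.info("stage simulate: seed=%d hash=%s", cfg.seed, cfg.config_hash)
        self.reference = simmod.generate_reference(
            cfg.n_transcripts,
            length_mean=cfg.length_mean,
            cds_fraction=cfg.cds_fraction,
            gc=cfg.gc,
            seed=cfg.seed,
            length_sd=cfg.length_sd,
        )
        self.truth = simmod.plant_variants(
            self.reference,
            {
                simmod.SHARED_POLYMORPHISM: cfg.n_shared,
                simmod.GROUP_EXCLUSIVE_FIXED: cfg.n_fixed,
                simmod.GROUP_EXCLUSIVE_POLYMORPHIC: cfg.n_group_poly,
            },
            seed=cfg.seed + 1,
            poly_frequency=cfg.poly_frequency,
            n_gap_alleles=cfg.n_gap_alleles,
            edge_margin=cfg.edge_margin,
        )
        simmod.assign_fold_changes(
            self.reference,
            self.truth,
            n_de=cfg.n_de,
            fold_range=(cfg.fold_min, cfg.fold_max),
            seed=cfg.seed + 2,
        )
        self.plans = simmod.make_sample_plans(
            self.reference,
            self.truth,
            n_ao=cfg.n_ao,
            n_lm=cfg.n_lm,
            reads_per_sample=cfg.reads_per_sample,
            seed=cfg.seed + 3,
            weight_sd_log2=cfg.weight_sd_log2,
            read_length_mean=cfg.read_length_mean,
            read_length_sd=cfg.read_length_sd,
            read_length_min=cfg.read_length_min,
            sub_rate=cfg.sub_rate,
            indel_rate=cfg.indel_rate,
        )
        self.reads = simmod.simulate_reads(self.reference, self.truth, self.plans, seed=cfg.seed + 4)
        simmod.write_fasta(self.reference, self.outdir / "reference.fasta")
        simmod.write_truth(self.truth, self.outdir / "truth.tsv", self.outdir / "truth.json")
        simmod.write_manifest(self.plans, self.outdir / "manifest.tsv")
        (self.outdir / "plans.json").write_text(
            json.dumps(
                [
                    {
                        "sample_id": p.sample_id,
                        "group": p.group,
                        "n_reads": p.n_reads,
                        "weights": list(p.weights),
                        "read_length_mean": p.read_length_mean,
                        "read_length_sd": p.read_length_sd,
                        "read_length_min": p.read_length_min,
                        "sub_rate": p.sub_rate,
                        "indel_rate": p.indel_rate,
                    }
                    for p in self.plans
                ]
            )
        )
        reads_dir = self.outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sid, reads in self.reads.items():
            simmod.write_fastq(reads, reads_dir / f"{sid}.fastq")
        logger.info("simulated %d samples", len(self.reads))
        self._stamp("simulate")

    def run_qc(self) -> None:
        assert self.reads is not None, "simulate stage must run first"
        cfg = self.config
        self.qc = qc_samples(self.reads, cfg.qc_min_reads, cfg.qc_min_mean_len)
        with open(self.outdir / "qc.tsv", "w") as fh:
            fh.write("sample\tn_reads\tmean_length\tpassed\n")
            for q in self.qc:
                fh.write(f"{q.sample_id}\t{q.n_reads}\t{q.mean_length:.1f}\t{q.passed}\n")
        for q in self.qc:
            if not q.passed:
                logger.warning(
                    "QC fail: %s (%d reads, mean %.0f bp) excluded from expression",
                    q.sample_id, q.n_reads, q.mean_length,
                )
        self._stamp("qc")

    def align(self) -> None:
        assert self.reference is not None and self.reads is not None
        if self._cached("align") and self._load_align():
            return
        cfg = self.config
        params = alignmod.AlignParams(
            k=cfg.k,
            min_identity=cfg.min_identity,
            match_score=cfg.match_score,
            mismatch_penalty=cfg.mismatch_penalty,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            max_gap=cfg.max_gap,
            seed_stride=cfg.seed_stride,
        )
        index = alignmod.build_index(self.reference, k=cfg.k)
        self.alignments = []
        for sid, reads in self.reads.items():
            alns = alignmod.align_reads(reads, index, self.reference, params, sample_id=sid)
            logger.info("aligned %d/%d reads for %s", len(alns), len(reads), sid)
            self.alignments.extend(alns)
        alignmod.write_sam(self.alignments, self.reference, self.outdir / "alignments.sam")
        self.pileup = alignmod.build_pileup(
            self.alignments, self.reference, list(self.reads.keys())
        )
        self._stamp("align")

    def call_snps(self) -> None:
        assert self.pileup is not None
        cfg = self.config
        self.snps = varmod.call_group_snps(
            self.pileup,
            self.reference,
            self.groups,
            min_depth=cfg.min_depth,
            min_allele_reads=cfg.min_allele_reads,
            freq_low=cfg.freq_low,
            freq_high=cfg.freq_high,
            present_min=cfg.present_min,
        )
        logger.info(
            "SNP funnel: %d putative -> %d filtered -> %d group-specific",
            len(self.snps.putative), len(self.snps.filtered), len(self.snps.group_specific),
        )
        varmod.write_snp_table(self.snps.group_specific, self.outdir / "group_specific_snps.tsv")
        varmod.write_vcf(self.snps.group_specific, self.reference, self.outdir / "group_specific_snps.vcf")
        self._stamp("snps")

    def expression(self) -> None:
        assert self.alignments is not None and self.qc is not None
        cfg = self.config
        passed = [q.sample_id for q in self.qc if q.passed]
        if len(passed) < 4:
            raise RuntimeError("fewer than 4 samples passed QC; cannot test expression")
        lengths = pd.Series({t.id: len(t) for t in self.reference})
        counts = exprmod.count_matrix(
            [a for a in self.alignments if a.sample_id in passed], passed
        )
        self.expr = exprmod.compute_rpkm(counts, lengths.loc[counts.index])
        self.expr.rpkm.to_csv(self.outdir / "rpkm.tsv", sep="\t")
        groups = {s: g for s, g in self.groups.items() if s in passed}
        self.de = exprmod.differential_expression(
            self.expr, groups, tier=cfg.de_tier, alpha=cfg.de_alpha, pseudocount=cfg.pseudocount
        )
        self.de.to_csv(self.outdir / "de_results.tsv", sep="\t")
        if len(self.de) >= 2:
            log_expr = self.expr.drop_unexpressed().log2.loc[self.de.index]
            clust = exprmod.cluster_expression(log_expr)
            gene_nwk, sample_nwk = exprmod.cluster_newick(clust)
            (self.outdir / "genes.nwk").write_text(gene_nwk + "\n")
            (self.outdir / "samples.nwk").write_text(sample_nwk + "\n")
            clust.ordered.to_csv(self.outdir / "heatmap.tsv", sep="\t")
        self._stamp("express")

    def stats(self) -> None:
        snps = self.snps
        de = self.de
        subtype_counts: dict[str, int] = {}
        fisher_table = None
        overlap = None
        n_loci = None
        if snps is not None:
            for s in snps.group_specific:
                subtype_counts[s.subtype] = subtype_counts.get(s.subtype, 0) + 1
            n_loci = len({s.transcript_id for s in snps.group_specific})
            fisher_table = statsmod.within_group_polymorphism_table(
                subtype_counts.get(varmod.POLY_AO, 0),
                subtype_counts.get(varmod.POLY_LM, 0),
                len(snps.group_specific),
            )
        if snps is not None and de is not None:
            snp_loci = {s.transcript_id for s in snps.group_specific}
            de_genes = set(de.index[de["significant"]])
            overlap = statsmod.snp_de_overlap(snp_loci, de_genes)
        n_total = sum(len(r) for r in self.reads.values()) if self.reads else None
        self.report = statsmod.pipeline_report(
            n_reads_total=n_total,
            n_reads_aligned=len(self.alignments) if self.alignments is not None else None,
            n_putative=len(snps.putative) if snps else None,
            n_filtered=len(snps.filtered) if snps else None,
            n_group_specific=len(snps.group_specific) if snps else None,
            n_loci=n_loci,
            subtype_counts=subtype_counts or None,
            tier_sizes={f"{self.config.de_tier:g}x": len(de)} if de is not None else None,
            n_de_significant=int(de["significant"].sum()) if de is not None else None,
            overlap=overlap,
            fisher_table=fisher_table,
        )
        statsmod.write_report(self.report, self.outdir / "report.json", self.outdir / "report.txt")
        self._stamp("stats")


def run_pipeline(config: RunConfig, resume: bool = False) -> PipelineRun:
    """Execute all stages in order; halts on the failing stage with partial
    outputs preserved on disk."""
    run = PipelineRun(config, resume=resume)
    for stage, fn in (
        ("simulate", run.simulate),
        ("qc", run.run_qc),
        ("align", run.align),
        ("snps", run.call_snps),
        ("express", run.expression),
        ("stats", run.stats),
    ):
        try:
            fn()
        except Exception:
            logger.error("stage %r failed; partial outputs kept in %s", stage, run.outdir)
            raise
    return run
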