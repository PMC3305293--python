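"""Synthetic two-population transcriptome read sets with known truth.

Emulates the data structure of a legacy 454 RNA-seq contrast between an
anadromous (AO) and a landlocked (LM) population: a reference transcript
set, planted variants of three classes (shared polymorphisms,
group-exclusive fixed differences, group-restricted polymorphisms, plus a
single-base gap-allele class), and non-normalized per-sample read sets
whose per-transcript read counts are multinomial in expression weights —
so read counts carry the expression signal that the downstream RPKM
analysis quantifies.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
GAP = "-"

#: variant classes
SHARED_POLYMORPHISM = "shared_polymorphism"
GROUP_EXCLUSIVE_FIXED = "group_exclusive_fixed"
GROUP_EXCLUSIVE_POLYMORPHIC = "group_exclusive_polymorphic"
VARIANT_CLASSES = (
    SHARED_POLYMORPHISM,
    GROUP_EXCLUSIVE_FIXED,
    GROUP_EXCLUSIVE_POLYMORPHIC,
)

GROUPS = ("AO", "LM")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceTranscript:
    """A transcript sequence; coordinates are 0-based half-open throughout.

    ``cds`` is an optional (start, end) interval with ``frame`` the offset of
    the first complete codon within it (0 for all generated transcripts).
    """

    id: str
    sequence: str
    cds: tuple[int, int] | None = None
    frame: int = 0

    def __post_init__(self):
        if set(self.sequence) - set(BASES):
            raise ValueError(f"{self.id}: non-ACGT characters in sequence")
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.id}: CDS {self.cds} outside sequence")
            if (e - s - self.frame) % 3 != 0:
                raise ValueError(f"{self.id}: CDS length not a codon multiple")

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedVariant:
    """A planted variant; ``alt`` is a single base or ``-`` (one-base gap)."""

    transcript_id: str
    position: int
    ref: str
    alt: str
    var_class: str
    group: str  # carrier group: AO, LM, or both
    frequency: float  # within-carrier-group alt frequency

    def __post_init__(self):
        if self.var_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if self.var_class == SHARED_POLYMORPHISM:
            if self.group != "both":
                raise ValueError("shared polymorphisms carry group='both'")
        elif self.group not in GROUPS:
            raise ValueError("group-exclusive variants need exactly one carrier group")
        if self.var_class == GROUP_EXCLUSIVE_FIXED and self.frequency != 1.0:
            raise ValueError("fixed variants must have frequency 1")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError("frequency must lie in (0, 1]")

    @property
    def is_indel(self) -> bool:
        return self.alt == GAP


@dataclass
class SamplePlan:
    """Read-generation plan for one sample (one sequencing library)."""

    sample_id: str
    group: str
    n_reads: int
    weights: np.ndarray  # per-transcript expression weights, sum to 1
    read_length_mean: float = 187.0
    read_length_sd: float = 60.0
    read_length_min: int = 40
    sub_rate: float = 0.005
    indel_rate: float = 0.002

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("read count must be positive")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("expression weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("expression weights must sum to a positive value")
        self.weights = w / total


@dataclass
class TruthSet:
    """Planted variants plus per-transcript true LM/AO expression fold change."""

    variants: list[PlantedVariant]
    fold_changes: dict[str, float]  # transcript id -> true fold change (LM/AO)
    seed: int

    def variants_for(self, transcript_id: str) -> list[PlantedVariant]:
        return [v for v in self.variants if v.transcript_id == transcript_id]


# ---------------------------------------------------------------------------
# reference generation


def _sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    # Per-sample stream keyed by a CRC of the sample id, so adding or
    # removing a sample never perturbs the reads of the others.
    key = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Sample codons with per-base GC probability, rejecting stop codons."""
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def generate_reference(
    n_transcripts: int,
    length_mean: float = 351.0,
    cds_fraction: float = 0.5,
    gc: float = 0.45,
    seed: int = 0,
    length_sd: float = 120.0,
    length_min: int = 100,
) -> list[ReferenceTranscript]:
    """Generate a synthetic transcript reference.

    ``cds_fraction`` of transcripts carry a CDS that starts with ATG, has no
    internal stop codon in frame, and ends with a stop codon; the remainder
    are noncoding.  Lengths follow a truncated normal (mean 351 bp by
    default, the scale of a short-read transcriptome assembly).
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if length_mean <= 0 or length_min <= 0:
        raise ValueError("transcript lengths must be positive")
    if not (0 <= cds_fraction <= 1 and 0 <= gc <= 1):
        raise ValueError("cds_fraction and gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = max(1, len(str(n_transcripts)))
    transcripts: list[ReferenceTranscript] = []
    for i in range(n_transcripts):
        length = int(max(length_min, round(rng.normal(length_mean, length_sd))))
        coding = rng.random() < cds_fraction
        tid = f"contig_{i:0{width}d}"
        if not coding:
            transcripts.append(ReferenceTranscript(tid, _random_seq(rng, length, gc)))
            continue
        # 5'UTR + [ATG + codons + stop] + 3'UTR, CDS >= 30 bp
        utr5 = int(rng.integers(0, max(1, length // 6)))
        utr3 = int(rng.integers(0, max(1, length // 6)))
        n_codons = max(10, (length - utr5 - utr3) // 3)
        body = _random_codons(rng, n_codons - 2, gc)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        cds_seq = "ATG" + body + stop
        seq = _random_seq(rng, utr5, gc) + cds_seq + _random_seq(rng, utr3, gc)
        transcripts.append(
            ReferenceTranscript(tid, seq, cds=(utr5, utr5 + len(cds_seq)), frame=0)
        )
    return transcripts


# ---------------------------------------------------------------------------
# variant planting


def plant_variants(
    reference: Sequence[ReferenceTranscript],
    n_per_class: Mapping[str, int],
    seed: int = 0,
    poly_frequency: float = 0.5,
    n_gap_alleles: int = 0,
    edge_margin: int = 5,
) -> TruthSet:
    """Plant variants of the requested classes at distinct random sites.

    Group-exclusive polymorphic variants always share their reference allele
    with the non-carrier group (the carrier group segregates ref/alt, the
    other group is fixed for ref).  ``n_gap_alleles`` of the planted variants
    (drawn from the fixed class first) use a single-base gap allele instead
    of a substitution; gap positions are left-normalized within homopolymer
    runs, matching the leftmost-gap convention of alignment, so planted and
    called coordinates agree.  Positions within ``edge_margin`` of a
    transcript end (capped so short transcripts keep usable interiors) are
    avoided so variants sit clear of the coverage taper near transcript ends.
    """
    unknown = set(n_per_class) - set(VARIANT_CLASSES)
    if unknown:
        raise ValueError(f"unknown variant classes: {sorted(unknown)}")
    n_total = sum(n_per_class.values())
    rng = np.random.default_rng(seed)
    # candidate sites: (transcript index, position); per-transcript margin
    sites = []
    for ti, t in enumerate(reference):
        margin = min(edge_margin, max(1, (len(t) - 50) // 2))
        sites.extend((ti, pos) for pos in range(margin, len(t) - margin))
    if n_total > len(sites):
        raise ValueError(
            f"requested {n_total} variants but only {len(sites)} usable sites"
        )
    order = iter(rng.permutation(len(sites)))
    labels = [c for c in VARIANT_CLASSES for _ in range(n_per_class.get(c, 0))]
    gap_budget = n_gap_alleles
    used: set[tuple[int, int]] = set()
    variants: list[PlantedVariant] = []
    group_cycle = 0
    for var_class in labels:
        use_gap = gap_budget > 0 and var_class == GROUP_EXCLUSIVE_FIXED
        while True:
            try:
                ti, pos = sites[next(order)]
            except StopIteration:
                raise ValueError("variant request exhausted the usable sites")
            t = reference[ti]
            if use_gap:  # left-align the deletion within its homopolymer run
                while pos > 1 and t.sequence[pos - 1] == t.sequence[pos]:
                    pos -= 1
            if (ti, pos) not in used:
                used.add((ti, pos))
                break
        ref_base = t.sequence[pos]
        if use_gap:
            gap_budget -= 1
            alt = GAP
        else:
            alt = rng.choice([b for b in BASES if b != ref_base])
        if var_class == SHARED_POLYMORPHISM:
            group, freq = "both", poly_frequency
        else:
            group = GROUPS[group_cycle % 2]
            group_cycle += 1
            freq = 1.0 if var_class == GROUP_EXCLUSIVE_FIXED else poly_frequency
        variants.append(
            PlantedVariant(t.id, pos, ref_base, str(alt), var_class, group, freq)
        )
    variants.sort(key=lambda v: (v.transcript_id, v.position))
    return TruthSet(variants=variants, fold_changes={}, seed=seed)


def assign_fold_changes(
    reference: Sequence[ReferenceTranscript],
    truth: TruthSet,
    n_de: int,
    fold_range: tuple[float, float] = (2.0, 200.0),
    seed: int = 0,
) -> TruthSet:
    """Assign true LM/AO expression fold changes to ``n_de`` transcripts.

    Fold magnitudes are log-uniform over ``fold_range`` (the study's
    observed spread runs from 2x to beyond 200x); direction alternates so
    both over- and under-expression in LM occur.  All other transcripts get
    fold change 1.
    """
    rng = np.random.default_rng(seed)
    if n_de > len(reference):
        raise ValueError("more DE transcripts requested than transcripts exist")
    idx = rng.choice(len(reference), size=n_de, replace=False)
    fc = {t.id: 1.0 for t in reference}
    lo, hi = fold_range
    for j, ti in enumerate(sorted(idx)):
        mag = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        fc[reference[ti].id] = mag if j % 2 == 0 else 1.0 / mag
    truth.fold_changes = fc
    return truth


def make_sample_plans(
    reference: Sequence[ReferenceTranscript],
    truth: TruthSet,
    n_ao: int = 4,
    n_lm: int = 3,
    reads_per_sample: int | Sequence[int] = 150_000,
    seed: int = 0,
    weight_sd_log2: float = 1.0,
    **plan_kwargs,
) -> list[SamplePlan]:
    """Build per-sample plans with a shared base expression profile.

    Base per-transcript weights are log-normal (spread ``weight_sd_log2``
    in log2 units); LM samples have the truth fold changes applied on top.
    Libraries are not normalized, so these weights are exactly what RPKM
    should recover up to length scaling.
    """
    rng = np.random.default_rng(seed)
    n_t = len(reference)
    base = np.exp2(rng.normal(0.0, weight_sd_log2, size=n_t))
    fc = np.array([truth.fold_changes.get(t.id, 1.0) for t in reference])
    n_samples = n_ao + n_lm
    if np.isscalar(reads_per_sample):
        counts = [int(reads_per_sample)] * n_samples
    else:
        counts = [int(c) for c in reads_per_sample]
        if len(counts) != n_samples:
            raise ValueError("reads_per_sample length must equal n_ao + n_lm")
    plans = []
    for i in range(n_samples):
        group = "AO" if i < n_ao else "LM"
        w = base * (fc if group == "LM" else 1.0)
        plans.append(
            SamplePlan(
                sample_id=f"{group}_{i + 1 if group == 'AO' else i - n_ao + 1}",
                group=group,
                n_reads=counts[i],
                weights=w,
                **plan_kwargs,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# read simulation


def _haplotype(
    transcript: ReferenceTranscript,
    variants: Sequence[PlantedVariant],
    carry: Sequence[bool],
) -> str:
    """Apply carried variants (right to left, so deletions don't shift)."""
    seq = transcript.sequence
    for v, c in sorted(zip(variants, carry), key=lambda x: -x[0].position):
        if not c:
            continue
        if v.alt == GAP:
            seq = seq[: v.position] + seq[v.position + 1 :]
        else:
            seq = seq[: v.position] + v.alt + seq[v.position + 1 :]
    return seq


def _apply_errors(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < sub_rate:
            out.append(BASES[(BASES.index(ch) + int(rng.integers(1, 4))) % 4])
        elif r < sub_rate + indel_rate:
            if rng.random() < 0.5:  # deletion: drop the base
                continue
            out.append(ch)  # insertion: duplicate-style extra base
            out.append(BASES[int(rng.integers(4))])
        else:
            out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    quality: str


def simulate_reads(
    reference: Sequence[ReferenceTranscript],
    truth: TruthSet,
    plans: Sequence[SamplePlan],
    seed: int = 0,
) -> dict[str, list[SimulatedRead]]:
    """Simulate per-sample read sets from variant-bearing haplotypes.

    For each read a transcript is drawn multinomially from the plan's
    weights; each planted variant carried by the sample's group is applied
    with its within-group frequency (a per-read Bernoulli draw, modelling a
    pooled library of individuals); reads start uniformly, lengths follow a
    truncated normal, strand is uniform, and per-base substitution/indel
    errors are applied at the plan's rates.  Quality strings are a constant
    Q30 placeholder.  Fully deterministic per (inputs, seed); per-sample
    streams are independent (see ``_sample_rng``).
    """
    by_transcript = {t.id: truth.variants_for(t.id) for t in reference}
    out: dict[str, list[SimulatedRead]] = {}
    for plan in plans:
        if len(plan.weights) != len(reference):
            raise ValueError(f"{plan.sample_id}: weight vector length mismatch")
        rng = _sample_rng(seed, plan.sample_id)
        t_idx = rng.choice(len(reference), size=plan.n_reads, p=plan.weights)
        reads: list[SimulatedRead] = []
        for rn, ti in enumerate(t_idx):
            t = reference[ti]
            if len(t) == 0:
                logger.warning("%s: zero-length transcript %s skipped", plan.sample_id, t.id)
                continue
            variants = by_transcript[t.id]
            carry = [
                (v.group in ("both", plan.group)) and rng.random() < v.frequency
                for v in variants
            ]
            hap = _haplotype(t, variants, carry)
            length = int(
                max(plan.read_length_min, round(rng.normal(plan.read_length_mean, plan.read_length_sd)))
            )
            length = min(length, len(hap))
            start = int(rng.integers(0, len(hap) - length + 1))
            seq = hap[start : start + length]
            seq = _apply_errors(rng, seq, plan.sub_rate, plan.indel_rate)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(
                SimulatedRead(f"{plan.sample_id}_r{rn}", seq, "?" * len(seq))
            )
        out[plan.sample_id] = reads
    return out


# ---------------------------------------------------------------------------
# serialization

def write_fasta(reference: Iterable[ReferenceTranscript], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for t in reference:
        desc = f"cds={t.cds[0]}-{t.cds[1]} frame={t.frame}" if t.cds else "noncoding"
        records.append(SeqRecord(Seq(t.sequence), id=t.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ReferenceTranscript]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cds = None
        frame = 0
        for tok in rec.description.split():
            if tok.startswith("cds="):
                a, b = tok[4:].split("-")
                cds = (int(a), int(b))
            elif tok.startswith("frame="):
                frame = int(tok[6:])
        out.append(ReferenceTranscript(rec.id, str(rec.seq).upper(), cds=cds, frame=frame))
    return out


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth(truth: TruthSet, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """TruthSet as TSV (positions 1-based on disk) and optionally JSON."""
    with open(tsv_path, "w") as fh:
        fh.write("transcript\tpos\tref\talt\tclass\tgroup\tfreq\n")
        for v in truth.variants:
            fh.write(
                f"{v.transcript_id}\t{v.position + 1}\t{v.ref}\t{v.alt}\t"
                f"{v.var_class}\t{v.group}\t{v.frequency:g}\n"
            )
    if json_path is not None:
        payload = {
            "seed": truth.seed,
            "variants": [
                {
                    "transcript": v.transcript_id,
                    "pos": v.position,
                    "ref": v.ref,
                    "alt": v.alt,
                    "class": v.var_class,
                    "group": v.group,
                    "freq": v.frequency,
                }
                for v in truth.variants
            ],
            "fold_changes": truth.fold_changes,
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))


def write_manifest(plans: Iterable[SamplePlan], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for p in plans:
            fh.write(f"{p.sample_id}\t{p.group}\n")
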