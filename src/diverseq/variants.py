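"""SNP calling from pileups: putative sites, the 25-75% raw-read frequency
filter, group-exclusivity classification, and coding-effect annotation.

A "group-exclusive" site carries at least one allele observed in reads of
only one population group (AO or LM).  Subtypes follow the field's usage:
``fixed_divergent`` when each group presents a single, different allele;
``polymorphic_in_AO``/``polymorphic_in_LM`` when one group segregates two
alleles, one of which the other group lacks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import ALLELES, GAP_CODE, Pileup
from .simulate import GAP, ReferenceTranscript

NOT_GROUP_SPECIFIC = "not_group_specific"
GROUP_EXCLUSIVE = "group_exclusive"
UNCALLABLE = "uncallable"

FIXED_DIVERGENT = "fixed_divergent"
POLY_AO = "polymorphic_in_AO"
POLY_LM = "polymorphic_in_LM"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"
INDEL = "indel"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class GroupAlleleProfile:
    """Allele read counts for one group at one site."""

    group: str
    counts: Mapping[str, int]
    present_min: int = 2

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def present(self) -> frozenset[str]:
        """Alleles supported by at least ``present_min`` reads."""
        return frozenset(a for a, c in self.counts.items() if c >= self.present_min)

    @property
    def ambiguous(self) -> frozenset[str]:
        """Alleles with support below ``present_min`` but above zero."""
        return frozenset(
            a for a, c in self.counts.items() if 0 < c < self.present_min
        )


@dataclass(frozen=True)
class SnpSite:
    """A filtered polymorphic site with its group classification."""

    transcript_id: str
    position: int  # 0-based
    ref_allele: str
    allele_counts: Mapping[str, int]  # pooled over samples
    group_counts: Mapping[str, Mapping[str, int]]  # group -> allele -> count
    classification: str = NOT_GROUP_SPECIFIC
    subtype: str | None = None
    coding_effect: str = UNKNOWN
    aa_change: str | None = None

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(sorted(self.allele_counts))

    @property
    def minor_fraction(self) -> float:
        counts = sorted(self.allele_counts.values(), reverse=True)
        return counts[1] / self.depth if len(counts) > 1 else 0.0

    @property
    def alt_alleles(self) -> tuple[str, ...]:
        return tuple(sorted(a for a in self.allele_counts if a != self.ref_allele))


def _column_site(
    tid: str,
    pos: int,
    arr: np.ndarray,
    samples: Sequence[str],
    groups: Mapping[str, str],
    min_allele_reads: int,
) -> SnpSite | None:
    pooled = arr.sum(axis=0)
    supported = {
        ALLELES[a]: int(pooled[a])
        for a in range(5)
        if pooled[a] >= min_allele_reads
    }
    if len(supported) < 2:
        return None
    # reference allele = consensus (majority base over all samples); the gap
    # allele never serves as reference
    base_counts = pooled.copy()
    base_counts[GAP_CODE] = -1
    ref = ALLELES[int(base_counts.argmax())]
    group_counts: dict[str, dict[str, int]] = {}
    for si, s in enumerate(samples):
        g = groups[s]
        gc = group_counts.setdefault(g, {a: 0 for a in supported})
        for a in supported:
            gc[a] += int(arr[si, ALLELES.index(a)])
    return SnpSite(
        transcript_id=tid,
        position=pos,
        ref_allele=ref,
        allele_counts=supported,
        group_counts=group_counts,
    )


def call_putative_snps(
    pileup: Pileup,
    groups: Mapping[str, str],
    min_depth: int = 10,
    min_allele_reads: int = 2,
) -> list[SnpSite]:
    """Emit every column with >=2 supported alleles and sufficient depth.

    An allele counts as supported with >= ``min_allele_reads`` pooled reads;
    site depth (over supported alleles) must reach ``min_depth``.
    """
    sites: list[SnpSite] = []
    for tid, counts in pileup.counts.items():
        pooled_depth = counts.sum(axis=(1, 2))
        for pos in np.nonzero(pooled_depth >= min_depth)[0]:
            site = _column_site(
                tid, int(pos), counts[pos], pileup.samples, groups, min_allele_reads
            )
            if site is not None and site.depth >= min_depth:
                sites.append(site)
    return sites


def filter_frequency(
    sites: Iterable[SnpSite], low: float = 0.25, high: float = 0.75
) -> list[SnpSite]:
    """Keep sites whose every non-reference allele fraction lies in [low, high].

    Fractions are over raw realigned reads at the site (supported alleles);
    boundaries are inclusive.  For multi-allelic sites every minor allele
    must satisfy the window.
    """
    if low >= high:
        raise ValueError("low must be < high")
    kept = []
    for s in sites:
        depth = s.depth
        fracs = [s.allele_counts[a] / depth for a in s.alt_alleles]
        if fracs and all(low <= f <= high for f in fracs):
            kept.append(s)
    return kept


def classify_group_specific(
    site: SnpSite, present_min: int = 2
) -> tuple[str, str | None]:
    """Classify a site's group-exclusivity from its per-group allele counts.

    An allele is *present* in a group with >= ``present_min`` reads and
    *absent* with 0 reads; a single supporting read is neither.  Group
    exclusivity needs a *witness* allele that is present in one group and
    strictly absent (0 reads) from the other — so a sequencing error can
    neither create exclusivity (one stray read is not presence) nor, by
    itself, destroy the evidence carried by the site's other alleles (a
    stray read disqualifies only the allele it touches).  A group with zero
    depth makes the site uncallable.
    """
    profiles = {
        g: GroupAlleleProfile(g, c, present_min) for g, c in site.group_counts.items()
    }
    if len(profiles) < 2 or any(p.depth == 0 for p in profiles.values()):
        return UNCALLABLE, None
    ao, lm = profiles["AO"], profiles["LM"]
    witness = any(
        a in ao.present and lm.counts.get(a, 0) == 0 for a in ao.present
    ) or any(a in lm.present and ao.counts.get(a, 0) == 0 for a in lm.present)
    if not witness:
        return NOT_GROUP_SPECIFIC, None
    return _classify_sets(ao.present, lm.present)


def _classify_sets(ao: frozenset[str], lm: frozenset[str]) -> tuple[str, str | None]:
    """Set-logic core: classification from the two present-allele sets."""
    if not ao or not lm:
        return UNCALLABLE, None
    excl_ao = ao - lm
    excl_lm = lm - ao
    if not excl_ao and not excl_lm:
        return NOT_GROUP_SPECIFIC, None
    if len(ao) == 1 and len(lm) == 1:
        return GROUP_EXCLUSIVE, FIXED_DIVERGENT
    ao_poly = len(ao) > 1 and bool(excl_ao)
    lm_poly = len(lm) > 1 and bool(excl_lm)
    if ao_poly and not lm_poly:
        return GROUP_EXCLUSIVE, POLY_AO
    if lm_poly and not ao_poly:
        return GROUP_EXCLUSIVE, POLY_LM
    # remaining case: both groups segregate private alleles (rare outside
    # simulations) — report the larger present set (AO on ties) as carrier
    return GROUP_EXCLUSIVE, POLY_AO if len(ao) >= len(lm) else POLY_LM


# ---------------------------------------------------------------------------
# coding effect

_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[1]
        _CODON_TABLE = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


def annotate_coding_effect(
    site: SnpSite, transcript: ReferenceTranscript
) -> SnpSite:
    """Annotate a site's coding effect against the transcript's CDS.

    Substitutions inside the CDS are translated in frame via the standard
    genetic code; a gap allele inside the CDS is an ``indel``; sites outside
    any CDS (or on noncoding transcripts) are ``noncoding``; a codon that
    cannot be resolved (frame places the site in a partial codon) is
    ``unknown``.  With several alternative alleles, any frameshifting gap
    dominates, then any nonsynonymous change.
    """
    pos = site.position
    if not (0 <= pos < len(transcript)):
        raise ValueError(
            f"{site.transcript_id}:{pos} outside transcript of length {len(transcript)}"
        )
    if transcript.cds is None:
        return replace(site, coding_effect=NONCODING, aa_change=None)
    cds_start, cds_end = transcript.cds
    first = cds_start + transcript.frame
    if not (first <= pos < cds_end):
        return replace(site, coding_effect=NONCODING, aa_change=None)
    effects = []
    for alt in site.alt_alleles:
        if alt == GAP:
            effects.append((INDEL, None))
            continue
        offset = pos - first
        codon_start = first + 3 * (offset // 3)
        codon = transcript.sequence[codon_start : codon_start + 3]
        if len(codon) < 3:
            effects.append((UNKNOWN, None))
            continue
        within = pos - codon_start
        ref_codon = codon[:within] + site.ref_allele + codon[within + 1 :]
        alt_codon = codon[:within] + alt + codon[within + 1 :]
        aa_from, aa_to = _translate(ref_codon), _translate(alt_codon)
        if aa_from == aa_to:
            effects.append((SYNONYMOUS, None))
        else:
            effects.append((NONSYNONYMOUS, f"{aa_from}→{aa_to}"))
    for kind in (INDEL, UNKNOWN, NONSYNONYMOUS):
        for eff, aa in effects:
            if eff == kind:
                return replace(site, coding_effect=eff, aa_change=aa)
    return replace(site, coding_effect=SYNONYMOUS, aa_change=None)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SnpCallSet:
    """The SNP-calling funnel: putative -> frequency-filtered -> group-specific."""

    putative: list[SnpSite]
    filtered: list[SnpSite]
    group_specific: list[SnpSite]


def call_group_snps(
    pileup: Pileup,
    reference: Sequence[ReferenceTranscript],
    groups: Mapping[str, str],
    min_depth: int = 10,
    min_allele_reads: int = 2,
    freq_low: float = 0.25,
    freq_high: float = 0.75,
    present_min: int = 2,
) -> SnpCallSet:
    """Run the full SNP funnel and annotate group-specific sites."""
    by_id = {t.id: t for t in reference}
    putative = call_putative_snps(pileup, groups, min_depth, min_allele_reads)
    filtered = filter_frequency(putative, freq_low, freq_high)
    specific = []
    for site in filtered:
        cls, subtype = classify_group_specific(site, present_min)
        if cls != GROUP_EXCLUSIVE:
            continue
        site = replace(site, classification=cls, subtype=subtype)
        site = annotate_coding_effect(site, by_id[site.transcript_id])
        specific.append(site)
    return SnpCallSet(putative=putative, filtered=filtered, group_specific=specific)


# ---------------------------------------------------------------------------
# output


def _group_allele_string(site: SnpSite, group: str) -> str:
    gc = site.group_counts.get(group, {})
    present = sorted(a for a, c in gc.items() if c >= 2)
    return ",".join(present) if present else "."


def write_snp_table(sites: Iterable[SnpSite], path: str | Path) -> None:
    """Tab-separated site table (1-based positions, per-group allele sets)."""
    with open(path, "w") as fh:
        fh.write(
            "transcript\tposition\tAO_alleles\tLM_alleles\tdepth\t"
            "classification\tsubtype\tcoding_effect\taa_change\n"
        )
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.position + 1}\t"
                f"{_group_allele_string(s, 'AO')}\t{_group_allele_string(s, 'LM')}\t"
                f"{s.depth}\t{s.classification}\t{s.subtype or '-'}\t"
                f"{s.coding_effect}\t{s.aa_change or '-'}\n"
            )


def write_vcf(
    sites: Iterable[SnpSite],
    reference: Sequence[ReferenceTranscript],
    path: str | Path,
) -> None:
    """One VCF record per site; per-group allele depths as the two samples."""
    import pysam

    header = pysam.VariantHeader()
    for t in reference:
        header.contigs.add(t.id, length=len(t))
    header.info.add("AOA", "1", "String", "Alleles present in the AO group")
    header.info.add("LMA", "1", "String", "Alleles present in the LM group")
    header.info.add("CLS", "1", "String", "Group-specificity classification")
    header.info.add("SUB", "1", "String", "Group-specificity subtype")
    header.info.add("EFF", "1", "String", "Coding effect")
    header.formats.add("AD", ".", "Integer", "Allelic depths (ref, alt...)")
    header.add_sample("AO")
    header.add_sample("LM")
    by_id = {t.id: t for t in reference}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda x: (x.transcript_id, x.position)):
            seq = by_id[s.transcript_id].sequence
            has_gap = GAP in s.alt_alleles
            if has_gap and s.position > 0:
                # anchored deletion representation
                pos0 = s.position - 1
                ref = seq[pos0 : s.position + 1]
                alts = [ref[0]] + [
                    ref[0] + a for a in s.alt_alleles if a != GAP
                ]
                order = [GAP] + [a for a in s.alt_alleles if a != GAP]
            else:
                pos0 = s.position
                ref = s.ref_allele
                alts = [a for a in s.alt_alleles if a != GAP] or None
                order = [a for a in s.alt_alleles if a != GAP]
            rec = vcf.new_record(
                contig=s.transcript_id,
                start=pos0,
                alleles=tuple([ref] + (alts if alts else ["."])) if alts else (ref, "."),
            )
            rec.info["AOA"] = _group_allele_string(s, "AO")
            rec.info["LMA"] = _group_allele_string(s, "LM")
            rec.info["CLS"] = s.classification
            if s.subtype:
                rec.info["SUB"] = s.subtype
            rec.info["EFF"] = s.coding_effect
            for g in ("AO", "LM"):
                gc = s.group_counts.get(g, {})
                rec.samples[g]["AD"] = [gc.get(s.ref_allele, 0)] + [
                    gc.get(a, 0) for a in order
                ]
            vcf.write(rec)
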