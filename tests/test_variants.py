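"""SNP funnel: putative calls, the 25-75% window, group classification
against an exhaustive set-logic oracle, and codon-level annotation."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from diverseq.align import Pileup
from diverseq.simulate import ReferenceTranscript
from diverseq.variants import (
    FIXED_DIVERGENT,
    GROUP_EXCLUSIVE,
    INDEL,
    NONCODING,
    NONSYNONYMOUS,
    NOT_GROUP_SPECIFIC,
    POLY_AO,
    POLY_LM,
    SYNONYMOUS,
    SnpSite,
    annotate_coding_effect,
    call_group_snps,
    call_putative_snps,
    classify_group_specific,
    filter_frequency,
    _classify_sets,
)

from _oracles import classify_allele_sets

GROUPS = {"ao1": "AO", "ao2": "AO", "lm1": "LM", "lm2": "LM"}
SAMPLES = list(GROUPS)


def _pileup_from_columns(columns):
    """columns: {pos: {sample: {allele: count}}} on one 50 bp transcript."""
    ref = [ReferenceTranscript("t", "A" * 50)]
    pile = Pileup(ref, SAMPLES)
    for pos, per_sample in columns.items():
        for sample, alleles in per_sample.items():
            si = SAMPLES.index(sample)
            for allele, n in alleles.items():
                pile.counts["t"][pos, si, "ACGT-".index(allele)] += n
    return pile


def _site(allele_counts, group_counts, ref="A", pos=10):
    return SnpSite("t", pos, ref, allele_counts, group_counts)


class TestPutativeCalls:
    def test_monomorphic_column_is_not_a_site(self):
        pile = _pileup_from_columns({5: {"ao1": {"A": 50}}})
        assert call_putative_snps(pile, GROUPS) == []

    def test_single_read_allele_is_noise(self):
        pile = _pileup_from_columns({5: {"ao1": {"A": 10, "G": 1}}})
        assert call_putative_snps(pile, GROUPS, min_allele_reads=2) == []

    def test_matches_brute_force_refilter(self, rng):
        pile = Pileup([ReferenceTranscript("t", "A" * 200)], SAMPLES)
        pile.counts["t"][:, :, :] = rng.integers(0, 4, size=(200, 4, 5))
        sites = call_putative_snps(pile, GROUPS, min_depth=10, min_allele_reads=2)
        called = {s.position for s in sites}
        expected = set()
        for pos in range(200):
            pooled = pile.counts["t"][pos].sum(axis=0)
            supported = pooled[pooled >= 2]
            if len(supported) >= 2 and supported.sum() >= 10:
                expected.add(pos)
        assert called == expected


class TestFrequencyFilter:
    def _biallelic(self, n_alt, n_ref=None, depth=100):
        if n_ref is None:
            n_ref = depth - n_alt
        return _site(
            {"A": n_ref, "G": n_alt},
            {"AO": {"A": n_ref // 2, "G": n_alt // 2},
             "LM": {"A": n_ref - n_ref // 2, "G": n_alt - n_alt // 2}},
        )

    def test_thirty_percent_site_kept(self):
        assert filter_frequency([self._biallelic(30)]) != []

    def test_half_kept_boundaries_inclusive(self):
        assert filter_frequency([self._biallelic(50)]) != []
        assert filter_frequency([self._biallelic(25)]) != []
        assert filter_frequency([self._biallelic(24)]) == []

    def test_sweep_matches_interval_oracle(self):
        for n_alt in range(5, 96, 5):
            site = self._biallelic(n_alt)
            kept = filter_frequency([site]) != []
            f = min(n_alt, 100 - n_alt) / 100  # ref allele = majority
            alt_frac = site.allele_counts[site.alt_alleles[0]] / 100
            assert kept == (0.25 <= alt_frac <= 0.75)

    def test_every_minor_allele_must_pass(self):
        polluted = _site(
            {"A": 60, "G": 38, "C": 2},
            {"AO": {"A": 30, "G": 38, "C": 1}, "LM": {"A": 30, "G": 0, "C": 1}},
        )
        assert filter_frequency([polluted]) == []

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            filter_frequency([], low=0.8, high=0.2)


class TestGroupClassification:
    def test_polymorphic_in_ao(self):
        # AO presents {A,G}, LM presents {G} only
        site = _site(
            {"A": 20, "G": 40},
            {"AO": {"A": 20, "G": 15}, "LM": {"A": 0, "G": 25}},
        )
        assert classify_group_specific(site) == (GROUP_EXCLUSIVE, POLY_AO)

    def test_fixed_divergent(self):
        site = _site(
            {"C": 20, "T": 25},
            {"AO": {"C": 20, "T": 0}, "LM": {"C": 0, "T": 25}},
            ref="T",
        )
        assert classify_group_specific(site) == (GROUP_EXCLUSIVE, FIXED_DIVERGENT)

    def test_shared_alleles_not_group_specific(self):
        site = _site(
            {"A": 30, "G": 30},
            {"AO": {"A": 15, "G": 15}, "LM": {"A": 15, "G": 15}},
        )
        assert classify_group_specific(site) == (NOT_GROUP_SPECIFIC, None)

    def test_single_stray_read_cannot_create_exclusivity(self):
        site = _site(
            {"A": 40, "G": 2},
            {"AO": {"A": 20, "G": 1}, "LM": {"A": 20, "G": 1}},
        )
        assert classify_group_specific(site)[0] == NOT_GROUP_SPECIFIC

    def test_single_stray_read_blocks_only_its_allele(self):
        # fixed divergent site with one stray T in LM: the C witness stands
        site = _site(
            {"C": 200, "T": 180},
            {"AO": {"C": 200, "T": 1}, "LM": {"C": 0, "T": 179}},
            ref="C",
        )
        assert classify_group_specific(site) == (GROUP_EXCLUSIVE, FIXED_DIVERGENT)

    def test_zero_depth_group_uncallable(self):
        site = _site(
            {"A": 20, "G": 5},
            {"AO": {"A": 20, "G": 5}, "LM": {"A": 0, "G": 0}},
        )
        assert classify_group_specific(site)[0] == "uncallable"

    def test_matches_exhaustive_set_enumeration(self):
        """All ordered pairs of nonempty allele subsets agree with the
        independent set-logic oracle."""
        alleles = "ACGT"
        subsets = [
            frozenset(c)
            for r in range(1, 5)
            for c in itertools.combinations(alleles, r)
        ]
        assert len(subsets) == 15
        for ao in subsets:
            for lm in subsets:
                assert _classify_sets(ao, lm) == classify_allele_sets(ao, lm), (ao, lm)

    def test_label_swap_symmetry(self):
        subsets = [
            frozenset(c)
            for r in (1, 2)
            for c in itertools.combinations("ACGT", r)
        ]
        swap = {POLY_AO: POLY_LM, POLY_LM: POLY_AO, FIXED_DIVERGENT: FIXED_DIVERGENT}
        for ao in subsets:
            for lm in subsets:
                if len(ao) == len(lm):  # size ties break toward AO by design
                    continue
                cls, sub = _classify_sets(ao, lm)
                cls2, sub2 = _classify_sets(lm, ao)
                assert cls == cls2
                assert sub2 == (swap[sub] if sub else None)


class TestCodingEffect:
    def _transcript(self, cds_seq, utr5="GG", utr3="CC"):
        seq = utr5 + cds_seq + utr3
        return ReferenceTranscript("t", seq, cds=(len(utr5), len(utr5) + len(cds_seq)))

    def _annotated(self, transcript, pos, ref, alt):
        site = _site({ref: 30, alt: 20}, {"AO": {ref: 30, alt: 0}, "LM": {ref: 0, alt: 20}}, ref=ref, pos=pos)
        return annotate_coding_effect(site, transcript)

    def test_third_position_wobble_is_synonymous(self):
        t = self._transcript("ATGGCA")
        out = self._annotated(t, 7, "A", "G")  # GCA -> GCG
        assert out.coding_effect == SYNONYMOUS

    def test_first_position_change_is_nonsynonymous(self):
        t = self._transcript("ATGGCA")
        out = self._annotated(t, 5, "G", "A")  # GCA -> ACA, Ala -> Thr
        assert out.coding_effect == NONSYNONYMOUS
        assert out.aa_change == "A→T"

    def test_utr_site_is_noncoding(self):
        t = self._transcript("ATGGCA")
        assert self._annotated(t, 0, "G", "A").coding_effect == NONCODING

    def test_gap_allele_in_cds_is_indel(self):
        t = self._transcript("ATGGCA")
        assert self._annotated(t, 5, "G", "-").coding_effect == INDEL

    def test_position_outside_transcript_raises(self):
        t = self._transcript("ATGGCA")
        site = _site({"A": 30, "G": 20}, {"AO": {"A": 30}, "LM": {"G": 20}}, pos=99)
        with pytest.raises(ValueError):
            annotate_coding_effect(site, t)

    def test_all_single_base_mutations_match_translation_oracle(self):
        """Every mutation of every codon position agrees with Biopython's
        translation of the mutated codon."""
        codon = "TGG"  # Trp: all 9 mutants change or stop
        for codon in ("TGG", "GCA", "TTA", "ATG"):
            t = self._transcript("ATG" + codon + "TAA", utr5="", utr3="")
            for within in range(3):
                pos = 3 + within
                ref = codon[within]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    out = self._annotated(t, pos, ref, alt)
                    mutated = codon[:within] + alt + codon[within + 1 :]
                    aa_ref = str(Seq(codon).translate())
                    aa_alt = str(Seq(mutated).translate())
                    expected = SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS
                    assert out.coding_effect == expected, (codon, pos, alt)
                    if expected == NONSYNONYMOUS:
                        assert out.aa_change == f"{aa_ref}→{aa_alt}"


class TestFunnelOnRecoveredData:
    def test_funnel_is_nested_and_exclusive_sites_are_valid(self, recovery_run):
        snps = recovery_run.snps
        assert len(snps.putative) >= len(snps.filtered) >= len(snps.group_specific)
        filtered_keys = {(s.transcript_id, s.position) for s in snps.filtered}
        putative_keys = {(s.transcript_id, s.position) for s in snps.putative}
        specific_keys = {(s.transcript_id, s.position) for s in snps.group_specific}
        assert specific_keys <= filtered_keys <= putative_keys
        for s in snps.group_specific:
            present = {
                g: {a for a, c in counts.items() if c >= 2}
                for g, counts in s.group_counts.items()
            }
            both = present["AO"] & present["LM"]
            assert present["AO"] != present["LM"]
            # at least one allele fully private to a group
            assert any(
                s.group_counts["LM"].get(a, 0) == 0 for a in present["AO"]
            ) or any(s.group_counts["AO"].get(a, 0) == 0 for a in present["LM"])

    def test_vcf_and_table_emitted(self, recovery_run):
        outdir = recovery_run.outdir
        vcf = (outdir / "group_specific_snps.vcf").read_text()
        assert vcf.count("\n") > 10 and "##fileformat=VCF" in vcf
        table = (outdir / "group_specific_snps.tsv").read_text().splitlines()
        assert table[0].startswith("transcript\tposition")
        assert len(table) - 1 == len(recovery_run.snps.group_specific)
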