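"""Divergence statistics and the pipeline report.

Covers the two small statistics the analysis hinges on — a two-sided
Fisher exact test on the counts of within-group-polymorphic sites among
group-specific SNPs (does one population retain more polymorphism at
divergent sites?) and the overlap between SNP-bearing loci and the most
differentially expressed genes — plus the report formatter that renders
the pipeline's funnel counts as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

_REL_TOL = 1.0 + 1e-7  # tolerance for "no more probable" comparisons


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table, rows = groups, columns = polymorphic / not polymorphic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("table cells must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_sided(table: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher exact p, probability-ordering convention.

    Fixing both margins, the p-value sums the hypergeometric probabilities
    of every table whose probability does not exceed (within a small
    relative tolerance) that of the observed table.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * _REL_TOL].sum())
    return min(p, 1.0)


def within_group_polymorphism_table(
    n_poly_ao: int, n_poly_lm: int, n_group_specific: int
) -> ContingencyTable2x2:
    """Build the 2x2 of polymorphic vs. non-polymorphic group-specific sites."""
    return ContingencyTable2x2(
        a=n_poly_ao,
        b=n_group_specific - n_poly_ao,
        c=n_poly_lm,
        d=n_group_specific - n_poly_lm,
    )


# ---------------------------------------------------------------------------
# SNP-locus / DE-gene overlap


@dataclass(frozen=True)
class OverlapSummary:
    n_snp_loci: int
    n_de_genes: int
    n_shared: int
    shared_fraction: float | None  # None when no SNP loci exist

    @property
    def percent(self) -> int | None:
        if self.shared_fraction is None:
            return None
        return round(100.0 * self.shared_fraction)


def snp_de_overlap(snp_loci: Iterable[str], de_genes: Iterable[str]) -> OverlapSummary:
    """Overlap between SNP-bearing loci and DE genes (id sets)."""
    snps, des = set(snp_loci), set(de_genes)
    shared = len(snps & des)
    return OverlapSummary(
        n_snp_loci=len(snps),
        n_de_genes=len(des),
        n_shared=shared,
        shared_fraction=shared / len(snps) if snps else None,
    )


# ---------------------------------------------------------------------------
# report


def format_percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Percentage string at a display precision, e.g. 22/6835 -> '0.3%'."""
    if denominator == 0:
        return "NA"
    pct = 100.0 * numerator / denominator
    return f"{pct:.{decimals}f}%"


@dataclass
class PipelineReport:
    """Funnel counts and derived statistics, with explicit gaps when a
    stage's output is missing."""

    values: dict = field(default_factory=dict)
    missing: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"values": self.values, "missing": self.missing}, indent=1, default=str)

    def render(self) -> str:
        lines = ["pipeline report", "=" * 40]
        for key, val in self.values.items():
            lines.append(f"{key:38s} {val}")
        for gap in self.missing:
            lines.append(f"{gap:38s} <missing>")
        return "\n".join(lines)


def pipeline_report(
    n_reads_total: int | None = None,
    n_reads_aligned: int | None = None,
    n_putative: int | None = None,
    n_filtered: int | None = None,
    n_group_specific: int | None = None,
    n_loci: int | None = None,
    subtype_counts: Mapping[str, int] | None = None,
    tier_sizes: Mapping[str, int] | None = None,
    n_de_significant: int | None = None,
    overlap: OverlapSummary | None = None,
    fisher_table: ContingencyTable2x2 | None = None,
) -> PipelineReport:
    """Assemble the run report; every percentage recomputes from its
    printed numerator/denominator."""
    rep = PipelineReport()
    v = rep.values
    if n_reads_total is not None and n_reads_aligned is not None:
        v["reads_total"] = n_reads_total
        v["reads_aligned"] = n_reads_aligned
        v["reads_aligned_pct"] = format_percent(n_reads_aligned, n_reads_total, 0)
        if n_reads_aligned == 0:
            v["warning"] = "no reads aligned"
    else:
        rep.missing.append("alignment stage")
    if n_putative is not None:
        v["putative_snps"] = n_putative
    if n_filtered is not None:
        v["frequency_filtered_snps"] = n_filtered
    if n_group_specific is not None and n_filtered is not None:
        v["group_specific_snps"] = n_group_specific
        v["group_specific_pct_of_filtered"] = format_percent(
            n_group_specific, n_filtered, 1
        )
    elif n_group_specific is None:
        rep.missing.append("variant stage")
    if n_loci is not None:
        v["group_specific_loci"] = n_loci
    if subtype_counts:
        for sub, cnt in sorted(subtype_counts.items()):
            v[f"subtype_{sub}"] = cnt
    if fisher_table is not None:
        v["fisher_table_a_b_c_d"] = (
            f"{fisher_table.a},{fisher_table.b},{fisher_table.c},{fisher_table.d}"
        )
        v["fisher_p_two_sided"] = round(fisher_exact_two_sided(fisher_table), 6)
    if tier_sizes:
        for name, size in tier_sizes.items():
            v[f"tier_{name}"] = size
    if n_de_significant is not None:
        v["de_significant"] = n_de_significant
    else:
        rep.missing.append("expression stage")
    if overlap is not None:
        v["snp_loci"] = overlap.n_snp_loci
        v["de_genes"] = overlap.n_de_genes
        v["snp_de_shared"] = overlap.n_shared
        if overlap.shared_fraction is not None:
            v["snp_de_shared_pct"] = format_percent(
                overlap.n_shared, overlap.n_snp_loci, 0
            )
    return rep


def write_report(report: PipelineReport, json_path: str | Path, text_path: str | Path) -> None:
    Path(json_path).write_text(report.to_json())
    Path(text_path).write_text(report.render() + "\n")
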