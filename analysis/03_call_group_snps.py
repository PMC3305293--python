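#!/usr/bin/env python
"""Run the SNP funnel: putative sites -> 25-75% window -> group-exclusive.

Every multi-allelic pileup column becomes a putative SNP; the 25-75%
raw-read frequency window removes low-frequency (error-dominated) and
near-fixed calls; the survivors are classified for group exclusivity and
annotated for coding effect.  Writes the VCF and the site table under
results/toy_run/ and prints the funnel with its truth comparison.
"""

from pathlib import Path

from diverseq.pipeline import PipelineRun, default_toy_config, snp_recovery_metrics

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "toy_run"


def main() -> None:
    cfg = default_toy_config(outdir=str(OUTDIR), seed=0)
    run = PipelineRun(cfg, resume=True)
    run.simulate()
    run.run_qc()
    run.align()
    run.call_snps()
    s = run.snps
    print(f"putative SNPs: {len(s.putative)}")
    print(f"after 25-75% window: {len(s.filtered)}")
    print(f"group-specific: {len(s.group_specific)} "
          f"in {len({x.transcript_id for x in s.group_specific})} loci")
    for site in s.group_specific:
        print(f"  {site.transcript_id}:{site.position + 1} {site.subtype} "
              f"({site.coding_effect}) depth={site.depth}")
    sens, fdp = snp_recovery_metrics(run)
    print(f"vs. planted truth (full funnel, default error rates): "
          f"sensitivity {sens:.2f}, FDP {fdp:.2f}")
    print("note: within-group polymorphisms planted at frequency 0.5 sit at "
          "pooled fractions f*(4/7) or f*(3/7) and mostly fall below the "
          "window — the recovery experiment (06) quantifies the funnel "
          "under conditions where the truth is recoverable")


if __name__ == "__main__":
    main()
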