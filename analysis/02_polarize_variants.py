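"""Polarize the synthetic SNPs with substitution-aware weighted parsimony.

Reads the run directory written by 01_simulate_data.py, estimates the
mutation-weight and outgroup-substitution matrices from the data itself
(polymorphism counts and ingroup/outgroup fixed differences), polarizes
every biallelic SNP with outgroup coverage, classifies mutations
(WS/SW/WW/SS, Ti/Tv, CpG/GpC context) and writes the polarized table.
The truth table is used only for the final error report.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from beegc import io, workflow

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(p_threshold: float = 0.9, min_depth: int = 5) -> None:
    simdir = RESULTS / "sim"
    if not (simdir / "manifest.json").exists():
        sys.exit("run analysis/01_simulate_data.py first")
    manifest = json.loads((simdir / "manifest.json").read_text())

    reference = io.read_fasta(simdir / "reference.fa")
    outgroup = io.read_fasta(simdir / "outgroup.fa")
    coverage = io.read_coverage_bed(
        simdir / "outgroup_coverage.bed", manifest["chrom_lengths"]
    )
    records, vcf_diag = io.read_vcf(simdir / "variants.vcf")
    print(f"read {len(records)} biallelic SNPs (skipped: {dict(vcf_diag)})")

    result = workflow.polarize_dataset(
        reference,
        outgroup,
        coverage,
        records,
        p_threshold=p_threshold,
        min_outgroup_depth=min_depth,
    )
    resolved, unresolved = result.resolved, result.unresolved
    print(f"filters removed {dict(result.removed)}")
    io.write_polarized(
        resolved,
        unresolved,
        simdir / "polarized.tsv",
        simdir / "unresolved.tsv",
    )
    print(f"polarized {len(resolved)} SNPs; {len(unresolved)} unresolved")

    truth = pd.read_csv(simdir / "truth_snps.tsv", sep="\t")
    anc = {(r.chrom, r.pos): r.ancestral for r in truth.itertuples()}
    report = []
    for mclass in ("WS", "SW", "WW", "SS"):
        sub = [s for s in resolved if s.mclass == mclass]
        if not sub:
            continue
        wrong = sum(
            1 for s in sub if s.ancestral != anc[(s.site.chrom, s.site.pos)]
        )
        report.append(
            {"labelled_class": mclass, "n": len(sub), "frac_mispolarized": wrong / len(sub)}
        )
    rep = pd.DataFrame(report)
    rep.to_csv(simdir / "polarization_error_report.tsv", sep="\t", index=False)
    print("mispolarization among resolved SNPs, by labelled class:")
    print(rep.to_string(index=False))


if __name__ == "__main__":
    main()
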