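"""Windowed population-genetic statistics and their correlations.

Computes theta_w, pi, Tajima's D, GC, CpG_O/E, divergence and mean rho in
100 kb windows partitioned by annotation element, then the regressions
the recombination analyses rest on: diversity vs rho, divergence vs rho,
GC vs rho, per element.  Also emits the 1 kb-window table used by the
rho-given-theta comparison.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from beegc import io, popgen

RESULTS = Path(__file__).resolve().parents[1] / "results"


def one_kb_table(reference, annotation, sites, rate_map) -> pd.DataFrame:
    """Per-1kb-window theta, rho, and coding/intergenic composition."""
    rows = []
    for chrom, seq in reference.items():
        labels = popgen.element_labels(len(seq), annotation, chrom)
        coding = labels == 0
        intergenic = labels == len(popgen.ELEMENT_PRIORITY) - 1
        pos = np.array([s.pos - 1 for s in sites if s.chrom == chrom])
        n = sites[0].n if sites else 0
        for start in range(0, len(seq) - 999, 1000):
            end = start + 1000
            S = int(((pos >= start) & (pos < end)).sum())
            cseq = seq[start:end]
            cod_bp = int(coding[start:end].sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "theta_w": popgen.watterson_theta(S, n, 1000),
                    "rho": popgen.aggregate_rho(rate_map, chrom, start, end),
                    "coding_bp": cod_bp,
                    "intergenic_bp": int(intergenic[start:end].sum()),
                    "coding_cpg_oe": (
                        popgen.cpg_oe(cseq) if cod_bp > 500 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def main() -> None:
    simdir = RESULTS / "sim"
    if not (simdir / "manifest.json").exists():
        sys.exit("run analysis/01_simulate_data.py first")
    manifest = json.loads((simdir / "manifest.json").read_text())

    reference = io.read_fasta(simdir / "reference.fa")
    outgroup = io.read_fasta(simdir / "outgroup.fa")
    coverage = io.read_coverage_bed(
        simdir / "outgroup_coverage.bed", manifest["chrom_lengths"]
    )
    annotation = io.read_gff3(simdir / "annotation.gff3")
    rate_map = io.read_rate_map(simdir / "rho_map.tsv")
    snps = io.read_polarized(simdir / "polarized.tsv")

    windows = popgen.partition_windows(
        reference,
        annotation,
        window_size=100_000,
        sites=snps,
        rate_map=rate_map,
        outgroup=outgroup,
        outgroup_mask=coverage,
    )
    windows.to_csv(RESULTS / "window_stats_100kb.tsv", sep="\t", index=False)
    overall = windows[windows.element == "all"]
    print(f"{len(overall)} windows of 100 kb:")
    print(
        overall[["theta_w", "pi", "tajimas_d", "gc", "cpg_oe", "divergence", "rho_mean"]]
        .mean()
        .to_string()
    )

    regs = []
    for element in ("all", "CDS", "intron", "intergenic"):
        sub = windows[windows.element == element]
        for yvar in ("theta_w", "pi", "divergence", "gc"):
            try:
                r = popgen.regress_r2(sub["rho_mean"], sub[yvar])
            except ValueError:
                continue
            regs.append(
                {
                    "element": element,
                    "y": yvar,
                    "x": "rho_mean",
                    "slope": r.slope,
                    "r2": r.r2,
                    "p": r.p,
                }
            )
    regdf = pd.DataFrame(regs)
    regdf.to_csv(RESULTS / "window_regressions.tsv", sep="\t", index=False)
    print("\nregressions on mean rho (100 kb windows):")
    print(regdf.to_string(index=False))

    kb = one_kb_table(reference, annotation, snps, rate_map)
    kb.to_csv(RESULTS / "window_stats_1kb.tsv", sep="\t", index=False)
    print(f"\nwrote {len(kb)} 1 kb windows for the rho-given-theta comparison")


if __name__ == "__main__":
    main()
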