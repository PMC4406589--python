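"""Estimate gBGC strength B and the AT mutational bias lambda.

Builds class-specific derived allele frequency spectra from the
polarized SNPs, fits the constant-gBGC model (globally, for transitions
and transversions separately, and in bins of local GC and recombination
rate), and derives lambda, the equilibrium GC content GC*, the
per-meiosis bias b and the crossover-rate rescaling of the rho map.
Also runs the polarization-free folded-spectrum contingency test and
the class frequency summaries.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from beegc import gbgc, io, popgen

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_E = 500_000  # effective population size of the emulated population


def local_gc(reference, snps, flank: int = 100) -> np.ndarray:
    out = np.empty(len(snps))
    for j, s in enumerate(snps):
        seq = reference[s.chrom]
        i = s.pos - 1
        out[j] = popgen.gc_content(
            seq[max(0, i - flank) : i] + seq[i + 1 : i + 1 + flank]
        )
    return out


def local_rho(rate_map, snps, window: int = 1000) -> np.ndarray:
    out = np.empty(len(snps))
    for j, s in enumerate(snps):
        start = ((s.pos - 1) // window) * window
        out[j] = popgen.aggregate_rho(rate_map, s.chrom, start, start + window)
    return out


def fit_row(label, fit):
    if fit is None:
        return {"dataset": label, "n_snps": 0}
    return {
        "dataset": label,
        "B": fit.B,
        "lambda": fit.lam,
        "e_ws": fit.e_ws,
        "e_sw": fit.e_sw,
        "e_n": fit.e_n,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "ci_b_lo": fit.ci_b[0] if fit.ci_b else np.nan,
        "ci_b_hi": fit.ci_b[1] if fit.ci_b else np.nan,
    }


def main(seed: int = 1) -> None:
    simdir = RESULTS / "sim"
    if not (simdir / "polarized.tsv").exists():
        sys.exit("run analysis/02_polarize_variants.py first")
    reference = io.read_fasta(simdir / "reference.fa")
    rate_map = io.read_rate_map(simdir / "rho_map.tsv")
    snps = io.read_polarized(simdir / "polarized.tsv")
    gc_context = float(np.mean([popgen.gc_content(s) for s in reference.values()]))

    rows = []
    sfs_all = gbgc.build_class_sfs(snps)
    sfs_all.to_frame().to_csv(RESULTS / "class_sfs.tsv", sep="\t", index=False)
    fit_all = gbgc.fit_M1star(sfs_all, seed=seed, gc=gc_context, profile_ci=True)
    rows.append(fit_row("all", fit_all))
    for titv in ("Ti", "Tv"):
        sub = [s for s in snps if s.titv == titv or s.mclass in ("WW", "SS")]
        fit = gbgc.fit_M1star(
            gbgc.build_class_sfs(sub), seed=seed, gc=gc_context, profile_ci=True
        )
        rows.append(fit_row(titv, fit))
    fits = pd.DataFrame(rows)
    fits.to_csv(RESULTS / "gbgc_fits.tsv", sep="\t", index=False)
    print("constant-gBGC fits (global and Ti/Tv-restricted):")
    print(fits.to_string(index=False))

    # binned fits: local GC (100 bp flanks) and rho (1 kb window)
    gc_vals = local_gc(reference, snps)
    rho_vals = local_rho(rate_map, snps)
    binned_rows = []
    for name, values, edges in (
        ("local_GC", gc_vals, np.quantile(gc_vals, np.linspace(0, 1, 6))),
        ("rho", rho_vals, np.quantile(rho_vals, np.linspace(0, 1, 6))),
    ):
        spec = gbgc.BinSpec(variable=name, edges=tuple(edges))
        fits_b = gbgc.binned_fits(
            snps, values, spec, seed=seed, gc=gc_context, n_starts=4
        )
        for b, fit in fits_b.items():
            row = fit_row(f"{name}[{edges[b]:.3g},{edges[b + 1]:.3g})", fit)
            binned_rows.append(row)
    binned = pd.DataFrame(binned_rows)
    binned.to_csv(RESULTS / "gbgc_fits_binned.tsv", sep="\t", index=False)
    print("\nbinned fits:")
    print(binned.to_string(index=False))

    # derived quantities from the global fit
    mean_rho = popgen.aggregate_rho(
        rate_map, "chr1", 0, int(rate_map["end"].max())
    )
    derived = {
        "B": fit_all.B,
        "lambda": fit_all.lam,
        "GC_star": gbgc.equilibrium_gc(fit_all.B, fit_all.lam),
        "b_per_meiosis": gbgc.b_from_B(fit_all.B, N_E, "haplodiploid"),
        "mean_rho_per_kb": mean_rho,
        "crossover_cM_per_Mb": gbgc.r_from_rho(mean_rho, N_E, "haplodiploid"),
    }
    (RESULTS / "gbgc_derived.json").write_text(json.dumps(derived, indent=2))
    print("\nderived quantities:")
    for k, v in derived.items():
        print(f"  {k}: {v:.4g}")

    # polarization-free folded test and class frequency summaries
    sites = [
        s.to_site()
        for s, _ in [(r, None) for r in io.read_vcf(simdir / "variants.vcf")[0]]
        if s.is_biallelic_snp
    ]
    folded = gbgc.folded_spectrum_test(sites)
    print(
        f"\nfolded W/S test: OR = {folded.odds_ratio:.2f}, p = {folded.p:.3g} "
        f"(table {folded.table.tolist()})"
    )
    summaries = gbgc.class_frequency_summaries(snps, seed=seed)
    summaries["cells"].to_csv(RESULTS / "class_mean_freqs.tsv", sep="\t", index=False)
    summaries["ratios"].to_csv(RESULTS / "class_freq_ratios.tsv", sep="\t", index=False)
    summaries["relative_spectra"].to_csv(
        RESULTS / "relative_spectra.tsv", sep="\t", index=False
    )
    print("\nclass mean derived allele frequencies:")
    print(summaries["cells"].to_string(index=False))
    print("\nratio summaries:")
    print(summaries["ratios"].to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
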