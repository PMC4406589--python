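"""Gene-class analyses: CpG, expression, methylation and crossover rate.

Builds the per-gene table (CDS CpG_O/E class, caste-expression classes,
germline-methylation metrics and classes, rho in CDS and flanking
regions), compares crossover rates between classes with gene-weighted
bootstrap CIs, and runs the rho-at-given-theta profile on 1 kb windows.
Recovered classes are checked against the generator truth.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from beegc import genes, io

RESULTS = Path(__file__).resolve().parents[1] / "results"


def build_gene_table(reference, annotation, mcpg, chrom_lengths, rate_map):
    cds = annotation[annotation.element == "CDS"]
    mcpg_by_chrom = {
        c: sub["pos"].to_numpy() for c, sub in mcpg.groupby("chrom")
    }
    rows = []
    for gene_id, g in cds.groupby("gene_id"):
        chrom = g.chrom.iloc[0]
        seq = reference[chrom]
        intervals = sorted(zip(g.start.astype(int), g.end.astype(int)))
        cds_seq = "".join(seq[s:e] for s, e in intervals)
        oe, cls = genes.gene_cpg_class(cds_seq)
        per_kb, prop, n_mcpg, n_cpg = genes.methylation_metrics(
            intervals, seq, mcpg_by_chrom.get(chrom, ())
        )
        span_rows = annotation[annotation.gene_id == gene_id]
        span = (int(span_rows.start.min()), int(span_rows.end.max()))
        other = [
            (int(r.start), int(r.end))
            for r in cds[cds.gene_id != gene_id].itertuples()
            if r.chrom == chrom
        ]
        rho_cds, rho_near, rho_far = genes.gene_region_rho(
            intervals, span, chrom, chrom_lengths[chrom], rate_map, other_cds=other
        )
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "cds_cpg_oe": oe,
                "cpg_class": cls,
                "mcpg_per_kb": per_kb,
                "prop_cpg_methylated": prop,
                "rho_cds": rho_cds,
                "rho_flank_near": rho_near,
                "rho_flank_far": rho_far,
            }
        )
    return pd.DataFrame(rows)


def main(seed: int = 1) -> None:
    simdir = RESULTS / "sim"
    if not (simdir / "manifest.json").exists():
        sys.exit("run analysis/01_simulate_data.py first")
    manifest = json.loads((simdir / "manifest.json").read_text())
    reference = io.read_fasta(simdir / "reference.fa")
    annotation = io.read_gff3(simdir / "annotation.gff3")
    rate_map = io.read_rate_map(simdir / "rho_map.tsv")
    mcpg = pd.read_csv(simdir / "mcpg_sites.tsv", sep="\t")

    table = build_gene_table(
        reference, annotation, mcpg, manifest["chrom_lengths"], rate_map
    )
    for scheme, col in (("qw", "expr_qw"), ("dw", "expr_dw")):
        lists_df = pd.read_csv(simdir / f"expression_{scheme}.tsv", sep="\t")
        lists = {
            label: sub["gene_id"].tolist()
            for label, sub in lists_df.groupby("class")
        }
        table, diag = genes.assign_expression_class(table, col, lists)
        if diag:
            print(f"expression scheme {scheme}: diagnostics {dict(diag)}")
    table["meth_class"] = genes.classify_methylation(table)
    table.to_csv(RESULTS / "gene_table.tsv", sep="\t", index=False)

    truth = pd.read_csv(simdir / "truth_genes.tsv", sep="\t")
    merged = table.merge(truth, on="gene_id")
    agree = (merged.cpg_class == merged.true_cpg_class).mean()
    print(f"{len(table)} genes; CpG class matches generator truth: {agree:.1%}")
    print(table["meth_class"].value_counts().to_string())

    comparisons = []
    for group_col in ("cpg_class", "expr_qw", "expr_dw", "meth_class"):
        for stat in ("rho_cds", "rho_flank_near", "rho_flank_far"):
            per_class, pairwise = genes.compare_gene_classes(
                table, group_col, stat, seed=seed
            )
            per_class.insert(0, "grouping", group_col)
            per_class.insert(1, "statistic", stat)
            comparisons.append(per_class)
    comp = pd.concat(comparisons, ignore_index=True)
    comp.to_csv(RESULTS / "gene_class_comparisons.tsv", sep="\t", index=False)
    print("\ncrossover rate by gene class (CDS and flanks):")
    print(
        comp[comp.grouping == "cpg_class"].to_string(index=False)
    )
    lcpg = comp[(comp.grouping == "cpg_class") & (comp["class"] == "LCpG")]
    hcpg = comp[(comp.grouping == "cpg_class") & (comp["class"] == "HCpG")]
    for stat in ("rho_cds", "rho_flank_near"):
        a = float(lcpg[lcpg.statistic == stat]["mean"].iloc[0])
        b = float(hcpg[hcpg.statistic == stat]["mean"].iloc[0])
        print(f"LCpG/HCpG mean {stat} ratio: {a / b:.2f}")

    kb_path = RESULTS / "window_stats_1kb.tsv"
    if kb_path.exists():
        kb = pd.read_csv(kb_path, sep="\t").rename(columns={})
        edges = np.nanquantile(kb["theta_w"], np.linspace(0, 1, 6))
        profile = genes.rho_given_theta_profile(kb, edges, seed=seed)
        profile.to_csv(RESULTS / "rho_given_theta.tsv", sep="\t", index=False)
        print("\nmean rho at given theta (1 kb windows):")
        print(profile.to_string(index=False))
    else:
        print("run analysis/03_window_statistics.py for the rho-given-theta profile")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
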