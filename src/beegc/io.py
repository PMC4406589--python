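"""File input/output: FASTA, VCF, GFF3, BED coverage masks and TSV tables.

Internal coordinates are 0-based half-open; VCF and GFF3 are written and
read 1-based with conversion at these boundaries only.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from beegc.variants import PolarizedSNP, SiteAlleles, Unresolved, VariantRecord


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write biallelic SNPs as an uncompressed VCF with diploid genotypes.

    ``variants`` columns: chrom, pos (1-based), ref, alt, k (alt copies),
    n (haploid sample size).  The k alt alleles are assigned to the first
    k haplotypes; haplotype identity carries no information here (sites
    are unlinked).
    """
    chroms = sorted(variants["chrom"].unique())
    n = int(variants["n"].iloc[0])
    n_dip = n // 2
    samples = [f"sample{i + 1:02d}" for i in range(n_dip)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for _, row in variants.iterrows():
            k = int(row["k"])
            gts = []
            for s in range(n_dip):
                h1 = 1 if 2 * s < k else 0
                h2 = 1 if 2 * s + 1 < k else 0
                gts.append(f"{h1}|{h2}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\t"
                f"PASS\tAC={k};AN={n}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], Counter]:
    """Read a VCF into variant records, skipping (and counting) records
    that are not biallelic SNPs."""
    records: list[VariantRecord] = []
    diagnostics: Counter = Counter()
    vcf = VCF(str(path))
    n = 2 * len(vcf.samples)
    for v in vcf:
        if len(v.ALT) != 1:
            diagnostics["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            diagnostics["indel"] += 1
            continue
        gts = np.array(v.genotypes)[:, :2]
        if (gts < 0).any():
            diagnostics["missing_genotypes"] += 1
            continue
        alt_count = int(gts.sum())
        if not 0 < alt_count < n:
            diagnostics["monomorphic"] += 1
            continue
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                alt_count=alt_count,
                n=n,
            )
        )
    return records, diagnostics


def annotate_sites(
    records: Iterable[VariantRecord],
    reference: Mapping[str, str],
    outgroup: Mapping[str, str] | None = None,
    coverage: Mapping[str, np.ndarray] | None = None,
    covered_depth: int = 20,
) -> list[SiteAlleles]:
    """Attach outgroup alleles/depth and reference flanking bases to
    biallelic variant records, yielding polarizable sites."""
    sites = []
    for r in records:
        if not r.is_biallelic_snp:
            continue
        seq = reference[r.chrom]
        i = r.pos - 1
        out_allele, depth = None, 0
        if outgroup is not None:
            o = outgroup[r.chrom][i].upper()
            out_allele = o if o in "ACGT" else None
            covered = coverage is None or bool(coverage[r.chrom][i])
            depth = covered_depth if covered else 0
        sites.append(
            SiteAlleles(
                chrom=r.chrom,
                pos=r.pos,
                allele_x=r.ref,
                allele_y=r.alts[0],
                count_y=r.alt_count,
                n=r.n,
                outgroup_allele=out_allele,
                outgroup_depth=depth,
                left_base=seq[i - 1].upper() if i > 0 else None,
                right_base=seq[i + 1].upper() if i + 1 < len(seq) else None,
            )
        )
    return sites


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table (0-based half-open) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in annotation.iterrows():
            attrs = f"ID={r['gene_id']}.{r['element']}.{r['start']};Parent={r['gene_id']}"
            fh.write(
                f"{r['chrom']}\tbeegc\t{r['element']}\t{r['start'] + 1}\t{r['end']}\t"
                f".\t{r.get('strand', '+')}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a 0-based half-open table (chrom, start, end,
    element, gene_id, strand)."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom", "source", "element", "start1", "end", "score", "strand",
            "frame", "attributes",
        ],
    )
    df["start"] = df["start1"] - 1
    df["gene_id"] = df["attributes"].str.extract(r"Parent=([^;]+)")
    return df[["chrom", "start", "end", "element", "gene_id", "strand"]]


def write_coverage_bed(
    masks: Mapping[str, np.ndarray], path: str | Path, depth: int = 20
) -> None:
    """Write covered runs of boolean masks as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(masks):
            m = np.asarray(masks[chrom], dtype=bool)
            padded = np.concatenate(([False], m, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for s, e in zip(edges[::2], edges[1::2]):
                fh.write(f"{chrom}\t{s}\t{e}\t{depth}\n")


def read_coverage_bed(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    df = pd.read_csv(
        str(path), sep="\t", header=None,
        names=["chrom", "start", "end", "depth"],
    )
    for _, r in df.iterrows():
        masks[r["chrom"]][int(r["start"]) : int(r["end"])] = True
    return masks


def write_rate_map(rate_map: pd.DataFrame, path: str | Path) -> None:
    rate_map[["chrom", "start", "end", "rho_per_kb"]].to_csv(
        path, sep="\t", index=False
    )


def read_rate_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def write_polarized(
    snps: Sequence[PolarizedSNP],
    unresolved: Sequence[Unresolved],
    path: str | Path,
    unresolved_path: str | Path | None = None,
) -> None:
    """Polarized SNPs as TSV (1-based positions); unresolved sites with
    reason codes in a companion file."""
    rows = [
        {
            "chrom": s.site.chrom,
            "pos": s.site.pos,
            "ancestral": s.ancestral,
            "derived": s.derived,
            "k": s.k,
            "n": s.site.n,
            "p_ancestral": s.p_ancestral,
            "mclass": s.mclass,
            "titv": s.titv,
            "context": ";".join(sorted(s.context)),
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if unresolved_path is not None:
        pd.DataFrame(
            [
                {"chrom": u.site.chrom, "pos": u.site.pos, "reason": u.reason}
                for u in unresolved
            ]
        ).to_csv(unresolved_path, sep="\t", index=False)


@dataclass(frozen=True)
class PolarizedRow:
    """A polarized SNP as read back from the TSV emitted by
    :func:`write_polarized` (duck-compatible with the SFS builders)."""

    chrom: str
    pos: int
    ancestral: str
    derived: str
    k: int
    n: int
    p_ancestral: float
    mclass: str
    titv: str
    context: frozenset

    @property
    def f_d(self) -> float:
        return self.k / self.n


def read_polarized(path: str | Path) -> list[PolarizedRow]:
    df = pd.read_csv(str(path), sep="\t", keep_default_na=False)
    return [
        PolarizedRow(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ancestral=r.ancestral,
            derived=r.derived,
            k=int(r.k),
            n=int(r.n),
            p_ancestral=float(r.p_ancestral),
            mclass=r.mclass,
            titv=r.titv,
            context=frozenset(str(r.context).split(";")) - {""},
        )
        for r in df.itertuples()
    ]


def write_run(run: Mapping, outdir: str | Path) -> dict[str, str]:
    """Write a full synthetic run directory with a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    write_fasta(run["reference"], outdir / "reference.fa")
    files["reference"] = "reference.fa"
    write_fasta(run["outgroup"], outdir / "outgroup.fa")
    files["outgroup"] = "outgroup.fa"
    write_gff3(run["annotation"], outdir / "annotation.gff3")
    files["annotation"] = "annotation.gff3"
    write_vcf(run["variants"], outdir / "variants.vcf")
    files["variants"] = "variants.vcf"
    write_coverage_bed(run["coverage"], outdir / "outgroup_coverage.bed")
    files["coverage"] = "outgroup_coverage.bed"
    write_rate_map(run["rho_map"], outdir / "rho_map.tsv")
    files["rho_map"] = "rho_map.tsv"
    run["mcpg"].to_csv(outdir / "mcpg_sites.tsv", sep="\t", index=False)
    files["mcpg"] = "mcpg_sites.tsv"
    for scheme, lists in run["expression_lists"].items():
        rows = [
            {"gene_id": g, "class": label}
            for label, gids in lists.items()
            for g in gids
        ]
        name = f"expression_{scheme}.tsv"
        pd.DataFrame(rows).to_csv(outdir / name, sep="\t", index=False)
        files[f"expression_{scheme}"] = name
    truth = run["truth"]
    truth.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
    truth.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    files.update(
        truth_snps="truth_snps.tsv",
        truth_regions="truth_regions.tsv",
        truth_genes="truth_genes.tsv",
    )
    cfg = run["config"]
    manifest = {
        "files": files,
        "seed": cfg.seed,
        "n_haplotypes": cfg.n_haplotypes,
        "chrom_lengths": dict(cfg.chrom_lengths),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return files
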