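"""Gene-level CpG, expression and germline-methylation classes.

Gene-body CpG depletion (low CpG observed/expected) is a signature of
germline methylation history, so genes are split into low/high CpG_O/E
classes (LCpG/HCpG) around a threshold, and independently into
experimentally supported methylation classes (HMET/LMET/UNMET) from
methylated-CpG site tables.  Crossover rates (population rho) are
compared between classes inside coding sequence and in flanking
noncoding regions, using gene-weighted bootstrap confidence intervals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from beegc.popgen import aggregate_rho, bootstrap_compare, cpg_oe


@dataclass
class GeneRecord:
    """Per-gene annotation with class assignments and regional rho."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple  # 0-based half-open (start, end) pairs
    cds_cpg_oe: float = np.nan
    cpg_class: str = "NA"
    expr_qw: str = "NA"
    expr_dw: str = "NA"
    mcpg_per_kb: float = np.nan
    prop_cpg_methylated: float = np.nan
    meth_class: str = "NA"
    rho_cds: float = np.nan
    rho_flank_near: float = np.nan
    rho_flank_far: float = np.nan


def gene_cpg_class(
    cds_seq: str, threshold: float = 1.19, min_len: int = 200
) -> tuple[float, str]:
    """CpG_O/E of a concatenated CDS (transcription orientation) and its
    class: HCpG when strictly above ``threshold``, else LCpG.

    The default threshold 1.19 is the gene-level split; 1.04 is used for
    the 1 kb-window variant.  Sequences shorter than ``min_len`` or with
    no C or no G give class NA.
    """
    if len(cds_seq) < min_len:
        return np.nan, "NA"
    oe = cpg_oe(cds_seq)
    if not np.isfinite(oe):
        return np.nan, "NA"
    return oe, "HCpG" if oe > threshold else "LCpG"


def assign_expression_class(
    genes: pd.DataFrame,
    scheme: str,
    lists: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, Counter]:
    """Tag genes with an expression class from caller-provided gene lists.

    ``scheme`` is the output column name (e.g. ``expr_qw`` or ``expr_dw``)
    and ``lists`` maps class labels (e.g. QgtW/WgtQ/NS) to gene-id lists.
    Genes absent from every list are NA; a gene claimed by more than one
    class in the scheme is excluded with a diagnostic; ids not present in
    ``genes`` are counted and skipped.
    """
    known = set(genes["gene_id"])
    assignment: dict[str, str] = {}
    diagnostics: Counter = Counter()
    conflicted: set[str] = set()
    for label in sorted(lists):
        for gid in lists[label]:
            if gid not in known:
                diagnostics["unknown_id"] += 1
                continue
            if gid in assignment and assignment[gid] != label:
                conflicted.add(gid)
                continue
            assignment[gid] = label
    for gid in conflicted:
        assignment.pop(gid, None)
        diagnostics["conflicting_membership"] += 1
    out = genes.copy()
    out[scheme] = out["gene_id"].map(assignment).fillna("NA")
    out.loc[out["gene_id"].isin(conflicted), scheme] = "NA"
    return out, diagnostics


def methylation_metrics(
    cds_intervals: Sequence[tuple[int, int]],
    chrom_seq: str,
    mcpg_positions: Sequence[int],
) -> tuple[float, float, int, int]:
    """Methylation metrics for one gene from a methylated-CpG site table.

    ``mcpg_positions`` are 0-based coordinates of the C of significantly
    methylated CpGs on the same chromosome.  Returns
    ``(mcpg_per_kb, prop_cpg_methylated, n_mcpg, n_cpg)``; the first two
    are NaN when the CDS contains no CpG site.
    """
    cds_len = sum(e - s for s, e in cds_intervals)
    n_cpg = 0
    for s, e in cds_intervals:
        seg = chrom_seq[s : min(e + 1, len(chrom_seq))].upper()
        n_cpg += sum(
            1 for i in range(min(e, len(chrom_seq) - 1) - s) if seg[i : i + 2] == "CG"
        )
    in_cds = [
        p for p in mcpg_positions if any(s <= p < e for s, e in cds_intervals)
    ]
    n_mcpg = len(in_cds)
    if n_cpg == 0 or cds_len == 0:
        return np.nan, np.nan, n_mcpg, n_cpg
    return n_mcpg / (cds_len / 1000.0), n_mcpg / n_cpg, n_mcpg, n_cpg


def classify_methylation(genes: pd.DataFrame) -> pd.Series:
    """HMET/LMET/UNMET classes from per-gene methylation proportions.

    Genes with zero methylated CpGs are UNMET.  Methylated genes are
    split into two equally sized classes on ``prop_cpg_methylated``
    (the proportion controls for CpG availability): the upper half is
    HMET, the lower LMET; ties at the boundary resolve by gene_id so the
    class sizes differ by at most one, with at-median ties preferring
    HMET.  Genes with no CpG sites are NA.
    """
    out = pd.Series("NA", index=genes.index, dtype=object)
    has_cpg = genes["prop_cpg_methylated"].notna()
    meth = has_cpg & (genes["prop_cpg_methylated"] > 0)
    out[has_cpg & ~meth] = "UNMET"
    sub = genes.loc[meth, ["gene_id", "prop_cpg_methylated"]].sort_values(
        ["prop_cpg_methylated", "gene_id"]
    )
    m = len(sub)
    if m:
        n_lmet = m // 2  # odd count puts the extra gene in HMET
        out[sub.index[:n_lmet]] = "LMET"
        out[sub.index[n_lmet:]] = "HMET"
    return out


def _subtract_intervals(
    intervals: list[tuple[int, int]], exclude: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    for xs, xe in sorted(exclude):
        nxt = []
        for s, e in intervals:
            if xe <= s or xs >= e:
                nxt.append((s, e))
                continue
            if s < xs:
                nxt.append((s, xs))
            if xe < e:
                nxt.append((xe, e))
        intervals = nxt
    return intervals


def _mean_rho(
    rate_map: pd.DataFrame, chrom: str, intervals: Sequence[tuple[int, int]]
) -> float:
    lengths, means = [], []
    for s, e in intervals:
        if e <= s:
            continue
        m = aggregate_rho(rate_map, chrom, s, e)
        if np.isfinite(m):
            lengths.append(e - s)
            means.append(m)
    if not lengths:
        return np.nan
    lengths = np.asarray(lengths, dtype=float)
    return float(np.sum(lengths * np.asarray(means)) / lengths.sum())


def gene_region_rho(
    cds_intervals: Sequence[tuple[int, int]],
    gene_span: tuple[int, int],
    chrom: str,
    chrom_len: int,
    rate_map: pd.DataFrame,
    other_cds: Sequence[tuple[int, int]] | None = None,
    near: tuple[int, int] = (10_000, 50_000),
    far: tuple[int, int] = (50_000, 100_000),
    noncoding_only: bool = True,
) -> tuple[float, float, float]:
    """Length-weighted mean rho in CDS and in geometric flanking regions.

    Flanks are spans of ``width`` starting ``offset`` away from each gene
    end (``near`` = (offset, width), default 50 kb starting 10 kb away;
    ``far`` default 100 kb starting 50 kb away), pooled over both sides
    regardless of strand, truncated at chromosome ends, and excluding
    other genes' CDS when ``noncoding_only``.  An empty usable flank is
    NaN.
    """
    rho_cds = _mean_rho(rate_map, chrom, cds_intervals)
    g_start, g_end = gene_span
    flanks = []
    for offset, width in (near, far):
        spans = [
            (max(0, g_start - offset - width), max(0, g_start - offset)),
            (min(chrom_len, g_end + offset), min(chrom_len, g_end + offset + width)),
        ]
        spans = [(s, e) for s, e in spans if e > s]
        if noncoding_only and other_cds:
            spans = _subtract_intervals(spans, other_cds)
        flanks.append(_mean_rho(rate_map, chrom, spans))
    return rho_cds, flanks[0], flanks[1]


def compare_gene_classes(
    genes: pd.DataFrame,
    group_col: str,
    stat_col: str,
    n_boot: int = 200,
    seed: int = 0,
    exclude_labels: tuple = ("NA",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class mean of a gene statistic with percentile bootstrap CIs.

    Classes are gene-weighted (one observation per gene).  Returns a
    per-class table (mean, CI, relative difference vs the overall mean of
    all included genes) and a pairwise table with two-sided bootstrap
    p-values for mean differences.
    """
    sub = genes[
        ~genes[group_col].isin(exclude_labels) & genes[stat_col].notna()
    ]
    groups = {
        str(label): grp[stat_col].to_numpy()
        for label, grp in sub.groupby(group_col)
    }
    if not groups:
        raise ValueError("no non-empty classes to compare")
    overall = float(sub[stat_col].mean())
    summaries, pairwise = bootstrap_compare(groups, n_boot=n_boot, seed=seed)
    per_class = pd.DataFrame(
        [
            {
                "class": s.label,
                "n": s.n,
                "mean": s.mean,
                "ci_lo": s.ci_lo,
                "ci_hi": s.ci_hi,
                "rel_diff_vs_overall": s.mean / overall - 1.0 if overall else np.nan,
            }
            for s in summaries.values()
        ]
    )
    return per_class, pairwise


def rho_given_theta_profile(
    windows: pd.DataFrame,
    theta_edges: Sequence[float],
    cpg_threshold: float = 1.04,
    min_element_bp: int = 500,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean rho by theta bin for coding vs intergenic 1 kb windows, and
    for LCpG vs HCpG coding windows.

    ``windows`` needs columns ``theta_w``, ``rho``, ``coding_bp``,
    ``intergenic_bp`` and ``coding_cpg_oe``; a window enters a group only
    when it spans more than ``min_element_bp`` of that element class.
    Supports the conditional comparison "rho at a given theta".
    """
    w = windows.copy()
    groups = {
        "coding": w["coding_bp"] > min_element_bp,
        "intergenic": w["intergenic_bp"] > min_element_bp,
        "LCpG": (w["coding_bp"] > min_element_bp)
        & (w["coding_cpg_oe"] <= cpg_threshold),
        "HCpG": (w["coding_bp"] > min_element_bp)
        & (w["coding_cpg_oe"] > cpg_threshold),
    }
    edges = np.asarray(theta_edges, dtype=float)
    rows = []
    for name, mask in groups.items():
        sub = w[mask & w["theta_w"].notna() & w["rho"].notna()]
        bin_idx = np.digitize(sub["theta_w"].to_numpy(), edges) - 1
        for b in range(len(edges) - 1):
            vals = sub["rho"].to_numpy()[bin_idx == b]
            if len(vals) == 0:
                continue
            summaries, _ = bootstrap_compare(
                {"x": vals}, n_boot=n_boot, seed=seed + b
            )
            s = summaries["x"]
            rows.append(
                {
                    "group": name,
                    "theta_lo": edges[b],
                    "theta_hi": edges[b + 1],
                    "n_windows": s.n,
                    "mean_rho": s.mean,
                    "ci_lo": s.ci_lo,
                    "ci_hi": s.ci_hi,
                }
            )
    return pd.DataFrame(rows)
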