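"""Windowed and per-element population-genetic statistics.

Watterson's theta, pairwise diversity pi, Tajima's D, GC content,
CpG observed/expected, ingroup-outgroup divergence and length-weighted
mean population recombination rate (rho), computed in fixed
non-overlapping windows partitioned by annotation element, plus the
ordinary-least-squares regression and class-bootstrap machinery used for
all correlation and class-comparison analyses.

Statistics that cannot be computed (no covered bases, no segregating
sites) are reported as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from beegc.variants import harmonic_number

#: annotation precedence used to resolve overlapping features
ELEMENT_PRIORITY = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic")


def watterson_theta(S: int, n: int, L: float) -> float:
    """Per-base Watterson estimator theta_w = S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if S < 0:
        raise ValueError("S must be >= 0")
    if L <= 0:
        return np.nan
    return S / (harmonic_number(n - 1) * L)


def nucleotide_diversity(ks: Sequence[int], n: int, L: float) -> float:
    """Per-base pairwise diversity pi = sum_j 2 k_j (n - k_j) / (n(n-1)) / L."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if L <= 0:
        return np.nan
    ks = np.asarray(ks, dtype=float)
    return float(np.sum(2.0 * ks * (n - ks)) / (n * (n - 1)) / L)


def tajimas_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from the number of segregating sites and total pairwise
    diversity (pi summed over sites, not per base).

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 of the
    original statistic.  Returns NaN when S == 0.
    """
    if S == 0:
        return np.nan
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def _valid_mask(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    return (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")


def gc_content(seq: str) -> float:
    """Proportion of G+C among unambiguous (ACGT) bases; NaN if none."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return np.nan
    return (seq.count("G") + seq.count("C")) / acgt


def dinucleotide_oe(seq: str, dinuc: str) -> float:
    """Observed/expected ratio of a dinucleotide over contiguous valid bases.

    ``(# dinuc occurrences, overlapping) * L_valid / (#first * #second)``
    where occurrences are only counted when the two bases are adjacent in
    the sequence and both unambiguous.  NaN when either single-base count
    is zero.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    seq = seq.upper()
    dinuc = dinuc.upper()
    n_first = seq.count(dinuc[0])
    n_second = seq.count(dinuc[1])
    if n_first == 0 or n_second == 0:
        return np.nan
    arr = np.frombuffer(seq.encode(), dtype="S1")
    valid = _valid_mask(seq)
    n_valid = int(valid.sum())
    hits = (
        (arr[:-1] == dinuc[0].encode())
        & (arr[1:] == dinuc[1].encode())
        & valid[:-1]
        & valid[1:]
    )
    return float(hits.sum()) * n_valid / (n_first * n_second)


def cpg_oe(seq: str) -> float:
    """CpG observed/expected ratio (low values indicate methylation history)."""
    return dinucleotide_oe(seq, "CG")


def gpc_oe(seq: str) -> float:
    """GpC observed/expected ratio (methylation-insensitive control)."""
    return dinucleotide_oe(seq, "GC")


def divergence(
    ingroup: str, outgroup: str, mask: np.ndarray | None = None
) -> float:
    """Per-base divergence between coordinate-aligned sequences.

    Comparable sites are positions inside ``mask`` (boolean, default all)
    where both sequences carry unambiguous bases.  NaN when there are no
    comparable sites.
    """
    if len(ingroup) != len(outgroup):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(ingroup.upper().encode(), dtype="S1")
    b = np.frombuffer(outgroup.upper().encode(), dtype="S1")
    comparable = _valid_mask(ingroup) & _valid_mask(outgroup)
    if mask is not None:
        comparable &= np.asarray(mask, dtype=bool)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return np.nan
    return float(((a != b) & comparable).sum()) / n_comp


def element_labels(length: int, annotation: pd.DataFrame, chrom: str) -> np.ndarray:
    """Per-base element label codes for one chromosome.

    ``annotation`` has columns chrom, start, end, element (0-based
    half-open).  Overlaps are resolved with precedence
    CDS > UTR > intron > intergenic; bases covered by no feature are
    intergenic.
    """
    codes = {e: i for i, e in enumerate(ELEMENT_PRIORITY)}
    labels = np.full(length, codes["intergenic"], dtype=np.uint8)
    rows = annotation[annotation["chrom"] == chrom]
    # paint lowest-priority first so higher-priority elements overwrite
    for element in reversed(ELEMENT_PRIORITY[:-1]):
        for _, r in rows[rows["element"] == element].iterrows():
            labels[int(r["start"]) : int(r["end"])] = codes[element]
    return labels


def aggregate_rho(
    rate_map: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """Length-weighted mean rho/kb of a rate map over [start, end).

    ``rate_map`` has columns chrom, start, end, rho_per_kb with intervals
    tiling each chromosome.  NaN when the window is uncovered.
    """
    rows = rate_map[rate_map["chrom"] == chrom]
    s = np.maximum(rows["start"].to_numpy(), start)
    e = np.minimum(rows["end"].to_numpy(), end)
    overlap = np.maximum(e - s, 0)
    total = overlap.sum()
    if total == 0:
        return np.nan
    return float(np.sum(overlap * rows["rho_per_kb"].to_numpy()) / total)


def partition_windows(
    reference: Mapping[str, str],
    annotation: pd.DataFrame,
    window_size: int = 100_000,
    sites: Sequence | None = None,
    rate_map: pd.DataFrame | None = None,
    outgroup: Mapping[str, str] | None = None,
    outgroup_mask: Mapping[str, np.ndarray] | None = None,
    min_covered: int = 200,
    last_window_min_frac: float = 0.5,
) -> pd.DataFrame:
    """Windowed statistics partitioned by annotation element.

    Windows are fixed and non-sliding, anchored at 0 on each chromosome;
    the final partial window is kept only if it spans at least
    ``last_window_min_frac`` of ``window_size``.  One output row per
    window x element plus an ``all`` row per window.  Element statistics
    with fewer than ``min_covered`` bases are NaN.

    ``sites`` are segregating sites (anything with ``chrom``, ``pos``
    1-based, ``count_y``/``k`` and ``n`` attributes); theta_w, pi and
    Tajima's D are computed from them over the element's covered bases.
    """
    site_index: dict[str, np.ndarray] = {}
    site_k: dict[str, np.ndarray] = {}
    n_hap = None
    if sites:
        by_chrom: dict[str, list] = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s)
            n_hap = s.n
        for chrom, ss in by_chrom.items():
            site_index[chrom] = np.array([s.pos - 1 for s in ss])
            site_k[chrom] = np.array(
                [getattr(s, "k", None) or s.count_y for s in ss]
            )

    rows = []
    for chrom in sorted(reference):
        seq = reference[chrom].upper()
        length = len(seq)
        labels = element_labels(length, annotation, chrom)
        pos = site_index.get(chrom, np.array([], dtype=int))
        ks = site_k.get(chrom, np.array([], dtype=int))
        n_windows = length // window_size
        if length % window_size >= last_window_min_frac * window_size:
            n_windows += 1
        for w in range(max(n_windows, 1) if length else 0):
            start = w * window_size
            end = min(start + window_size, length)
            win_labels = labels[start:end]
            in_win = (pos >= start) & (pos < end)
            wpos, wks = pos[in_win], ks[in_win]
            groups: list[tuple[str, np.ndarray]] = [
                ("all", np.ones(end - start, dtype=bool))
            ]
            for code, element in enumerate(ELEMENT_PRIORITY):
                groups.append((element, win_labels == code))
            for element, emask in groups:
                covered = int(emask.sum())
                row = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "element": element,
                    "covered_bases": covered,
                }
                if covered < min_covered:
                    rows.append(row)
                    continue
                eseq = "".join(
                    np.frombuffer(seq[start:end].encode(), dtype="S1")[emask]
                    .tobytes()
                    .decode()
                )
                row["gc"] = gc_content(eseq)
                row["cpg_oe"] = cpg_oe(eseq) if len(eseq) >= 2 else np.nan
                if sites:
                    snp_in = emask[wpos - start]
                    eks = wks[snp_in]
                    S = len(eks)
                    row["S"] = S
                    row["theta_w"] = watterson_theta(S, n_hap, covered)
                    row["pi"] = nucleotide_diversity(eks, n_hap, covered)
                    pi_total = row["pi"] * covered if covered else np.nan
                    row["tajimas_d"] = (
                        tajimas_d(S, pi_total, n_hap) if S > 0 else np.nan
                    )
                if outgroup is not None:
                    out_seq = outgroup[chrom][start:end]
                    sub_mask = emask.copy()
                    if outgroup_mask is not None:
                        sub_mask &= np.asarray(
                            outgroup_mask[chrom][start:end], dtype=bool
                        )
                    row["divergence"] = divergence(
                        seq[start:end], out_seq, sub_mask
                    )
                    if sites and np.isfinite(row.get("divergence", np.nan)):
                        div = row["divergence"]
                        row["diversity_over_divergence"] = (
                            row["pi"] / div if div > 0 else np.nan
                        )
                if rate_map is not None:
                    row["rho_mean"] = aggregate_rho(rate_map, chrom, start, end)
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Regression:
    slope: float
    intercept: float
    r2: float
    p: float


def regress_r2(x: Sequence[float], y: Sequence[float]) -> Regression:
    """Ordinary least squares y ~ x with R^2 and two-sided slope p-value.

    Pairs with non-finite values are dropped; at least 3 finite pairs and
    non-zero variance in x are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return Regression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
    )


@dataclass
class ClassSummary:
    label: str
    n: int
    mean: float
    ci_lo: float
    ci_hi: float
    degenerate: bool = False


def bootstrap_compare(
    values_by_class: Mapping[str, Sequence[float]],
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[dict[str, ClassSummary], pd.DataFrame]:
    """Percentile bootstrap CIs per class and pairwise difference p-values.

    Each class is resampled with replacement ``n_boot`` times; CIs are
    percentile intervals of the bootstrap means.  The two-sided p-value
    for a pairwise mean difference is the (add-one smoothed) fraction of
    bootstrap differences on the far side of zero, doubled.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2
    boots: dict[str, np.ndarray] = {}
    summaries: dict[str, ClassSummary] = {}
    for label in sorted(values_by_class):
        vals = np.asarray(values_by_class[label], dtype=float)
        if len(vals) == 0:
            raise ValueError(f"class {label!r} is empty")
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        means = vals[idx].mean(axis=1)
        boots[label] = means
        lo, hi = np.quantile(means, [alpha, 1 - alpha])
        summaries[label] = ClassSummary(
            label=label,
            n=len(vals),
            mean=float(vals.mean()),
            ci_lo=float(lo),
            ci_hi=float(hi),
            degenerate=len(vals) == 1,
        )
    pairs = []
    labels = sorted(values_by_class)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diff = boots[a] - boots[b]
            p_lo = (np.sum(diff <= 0) + 1) / (n_boot + 1)
            p_hi = (np.sum(diff >= 0) + 1) / (n_boot + 1)
            pairs.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "mean_diff": summaries[a].mean - summaries[b].mean,
                    "p": float(min(1.0, 2 * min(p_lo, p_hi))),
                }
            )
    return summaries, pd.DataFrame(pairs)
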