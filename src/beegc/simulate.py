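"""Synthetic genomes, SNPs, recombination maps and gene tables with truth.

The generator emulates the study conditions of a honeybee-like population
resequencing experiment: n = 60 sampled haplotypes, a low-GC genome
(~34%) with element-specific composition (CDS 39%, introns 23%,
intergenic 31%) and CpG enrichment, a strongly AT-biased mutation process
(lambda ~ 12), gBGC acting on weak/strong variants (transition-specific
B), ~3% outgroup divergence generating realistic polarization errors, a
piecewise-constant recombination map with planted gene-class effects, and
caste-expression / germline-methylation gene tables.

Derived-allele population frequencies are drawn directly from the
stationary sojourn density phi(x; B) discretized on a fine grid, followed
by binomial sampling of n haplotypes conditioned on segregation - sites
are independent (no linkage) and there is no explicit demography, which
is sufficient to exercise every estimator in the pipeline.  All
randomness flows through one seeded generator per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from beegc.gbgc import (
    ClassSFS,
    GbgcFit,
    expected_class_spectrum,
    expected_observed_spectra,
    sojourn_density,
)

BASES = "ACGT"
_BI = {b: i for i, b in enumerate(BASES)}
_W_BASES = (0, 3)  # A, T
_S_BASES = (1, 2)  # C, G
#: transition partner of each base (A<->G, C<->T)
_TI = {0: 2, 2: 0, 1: 3, 3: 1}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int
    n_haplotypes: int = 60
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    # per-element composition targets (GC proportion, CpG observed/expected)
    element_gc: Mapping[str, float] = field(
        default_factory=lambda: {
            "CDS": 0.39,
            "five_prime_UTR": 0.31,
            "three_prime_UTR": 0.24,
            "intron": 0.23,
            "intergenic": 0.31,
        }
    )
    element_cpg_oe: Mapping[str, float] = field(
        default_factory=lambda: {
            "CDS": 1.04,
            "five_prime_UTR": 1.3,
            "three_prime_UTR": 1.3,
            "intron": 1.7,
            "intergenic": 1.7,
        }
    )
    # gene structure (bp); ~57 genes/Mb as in a 13k-gene, 229 Mb genome
    spacer_range: tuple[int, int] = (4_000, 20_000)
    n_exons_range: tuple[int, int] = (3, 7)
    exon_len_range: tuple[int, int] = (150, 450)
    intron_len_range: tuple[int, int] = (100, 1_500)
    utr5_len: int = 200
    utr3_len: int = 300
    # planted gene CpG classes: CDS composition targets per class
    frac_lcpg: float = 0.5
    lcpg_cds_cpg_oe: float = 0.6
    hcpg_cds_cpg_oe: float = 1.6
    # recombination map (rho per kb)
    rho_mean: float = 390.0
    rho_sd: float = 167.0
    rho_segment_mean_len: int = 5_000
    gene_class_rho_mult: Mapping[str, float] = field(
        default_factory=lambda: {"LCpG": 1.0, "HCpG": 3.37}
    )
    # mutation and gBGC model
    theta_ws: float = 0.003  # W->S polymorphisms per W base
    lam: float = 12.0  # AT mutational bias; SW rate per S base = lam * theta_ws
    theta_ww: float = 0.0015  # W->W polymorphisms per W base
    theta_ss: float = 0.0015  # S->S polymorphisms per S base
    ti_fraction: float = 0.67  # P(transition) within the WS and SW classes
    B_ti: float = 6.47
    B_tv: float = 0.03
    # outgroup lineage
    outgroup_branch: float = 0.03  # expected substitutions per site
    outgroup_ti_fraction: float = 0.5
    outgroup_coverage: float = 0.95
    outgroup_covered_depth: int = 20
    outgroup_gap_len: int = 1_000
    # gene tables
    meth_prob: Mapping[str, float] = field(
        default_factory=lambda: {"LCpG": 0.39, "HCpG": 0.14}
    )
    meth_level: Mapping[str, float] = field(
        default_factory=lambda: {"LCpG": 0.60, "HCpG": 0.18}
    )
    expr_assoc: float = 0.5  # CpG-class association strength of expression
    sfs_only: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("theta_ws", "theta_ww", "theta_ss", "lam", "outgroup_branch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ti_fraction", "outgroup_ti_fraction", "outgroup_coverage",
                     "frac_lcpg", "expr_assoc"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic data."""

    snps: pd.DataFrame
    regions: pd.DataFrame
    genes: pd.DataFrame


# ---------------------------------------------------------------------------
# genome


def markov_chain_params(
    gc: float, cpg_oe_target: float, tol_gc: float = 1e-4, tol_oe: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """First-order Markov transition matrix and stationary distribution
    hitting a target GC proportion and CpG observed/expected ratio.

    Rows A, G, T emit bases independently from a composition vector; the
    C row's C->G probability is boosted (or damped), and the composition
    is re-calibrated by fixed-point iteration so the *stationary* GC and
    CpG_O/E match the targets.  Raises for infeasible combinations, with
    the feasible CpG_O/E range for the requested GC.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    max_oe = 0.98 / (gc / 2)
    if not 0 < cpg_oe_target <= max_oe:
        raise ValueError(
            f"CpG_O/E {cpg_oe_target} infeasible at GC={gc}; feasible range "
            f"(0, {max_oe:.2f}]"
        )
    gc_w, oe_w = gc, cpg_oe_target
    trans, pi = None, None
    for _ in range(500):
        p = np.array([(1 - gc_w) / 2, gc_w / 2, gc_w / 2, (1 - gc_w) / 2])
        t_cg = min(oe_w * p[2], 0.98)
        trans = np.tile(p, (4, 1))
        row_c = p * (1 - t_cg) / (1 - p[2])
        row_c[2] = t_cg
        trans[1] = row_c
        # stationary distribution of the chain
        vals, vecs = np.linalg.eig(trans.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = pi / pi.sum()
        gc_real = pi[1] + pi[2]
        oe_real = t_cg / pi[2]
        if abs(gc_real - gc) < tol_gc and abs(oe_real - cpg_oe_target) < tol_oe:
            break
        gc_w = min(max(gc_w * gc / gc_real, 0.02), 0.98)
        oe_w = oe_w * cpg_oe_target / oe_real
    return trans, pi


def _sample_markov(
    length: int, trans: np.ndarray, pi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a base-index array from a first-order Markov chain."""
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    if length == 0:
        return out
    out[0] = np.searchsorted(np.cumsum(pi), u[0])
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return out


def _gene_structure(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """(element, length) parts of one gene in transcription order."""
    n_exons = int(rng.integers(*config.n_exons_range))
    parts = [("five_prime_UTR", config.utr5_len)]
    for i in range(n_exons):
        parts.append(("CDS", int(rng.integers(*config.exon_len_range))))
        if i < n_exons - 1:
            parts.append(("intron", int(rng.integers(*config.intron_len_range))))
    parts.append(("three_prime_UTR", config.utr3_len))
    return parts


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate a reference genome, gene annotation and per-gene truth.

    Genes (5'UTR - exons/introns - 3'UTR) are placed without overlap,
    separated by intergenic spacers; every element's sequence comes from
    a Markov chain calibrated to that element's composition targets, with
    per-gene CDS CpG_O/E planted at the gene's LCpG or HCpG class target.

    Returns ``(reference, annotation, gene_truth)``; annotation is a
    0-based half-open table (chrom, start, end, element, gene_id).
    """
    rng = config.rng() if rng is None else rng
    chains = {
        el: markov_chain_params(config.element_gc[el], config.element_cpg_oe[el])
        for el in config.element_gc
    }
    class_chains = {
        "LCpG": markov_chain_params(config.element_gc["CDS"], config.lcpg_cds_cpg_oe),
        "HCpG": markov_chain_params(config.element_gc["CDS"], config.hcpg_cds_cpg_oe),
    }
    reference: dict[str, str] = {}
    ann_rows, gene_rows = [], []
    gene_no = 0
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        seq_parts: list[np.ndarray] = []
        cursor = 0
        while cursor < length:
            spacer = int(rng.integers(*config.spacer_range))
            structure = _gene_structure(config, rng)
            gene_len = sum(l for _, l in structure)
            if cursor + spacer + gene_len > length:
                # fill the remainder with intergenic sequence
                trans, pi = chains["intergenic"]
                seq_parts.append(_sample_markov(length - cursor, trans, pi, rng))
                cursor = length
                break
            trans, pi = chains["intergenic"]
            seq_parts.append(_sample_markov(spacer, trans, pi, rng))
            cursor += spacer
            gene_no += 1
            gene_id = f"gene{gene_no:05d}"
            cpg_class = "LCpG" if rng.random() < config.frac_lcpg else "HCpG"
            strand = "+" if rng.random() < 0.5 else "-"
            g_start = cursor
            for element, plen in structure:
                if element == "CDS":
                    trans, pi = class_chains[cpg_class]
                else:
                    trans, pi = chains[element]
                seq_parts.append(_sample_markov(plen, trans, pi, rng))
                ann_rows.append(
                    {
                        "chrom": chrom,
                        "start": cursor,
                        "end": cursor + plen,
                        "element": element,
                        "gene_id": gene_id,
                        "strand": strand,
                    }
                )
                cursor += plen
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": g_start,
                    "end": cursor,
                    "strand": strand,
                    "true_cpg_class": cpg_class,
                    "target_cds_cpg_oe": (
                        config.lcpg_cds_cpg_oe
                        if cpg_class == "LCpG"
                        else config.hcpg_cds_cpg_oe
                    ),
                }
            )
        codes = np.concatenate(seq_parts) if seq_parts else np.empty(0, dtype=np.int8)
        reference[chrom] = base_arr[codes].tobytes().decode()
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "element", "gene_id", "strand"]
    )
    gene_truth = pd.DataFrame(gene_rows)
    return reference, annotation, gene_truth


# ---------------------------------------------------------------------------
# recombination map


def simulate_rho_map(
    config: SimConfig,
    gene_truth: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Piecewise-constant rho/kb map tiling every chromosome.

    Segment lengths are exponential around ``rho_segment_mean_len``;
    values are lognormal with the configured mean and standard deviation.
    When gene truth and annotation are supplied, each gene's CDS intervals
    are overlaid with the planted per-class rho multiplier.
    """
    rng = config.rng() if rng is None else rng
    sigma2 = np.log1p((config.rho_sd / config.rho_mean) ** 2)
    mu = np.log(config.rho_mean) - sigma2 / 2
    rows = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        pos = 0
        while pos < length:
            seg = max(200, int(rng.exponential(config.rho_segment_mean_len)))
            end = min(pos + seg, length)
            rho = float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
            rows.append({"chrom": chrom, "start": pos, "end": end, "rho_per_kb": rho})
            pos = end
    base = pd.DataFrame(rows)
    if gene_truth is None or annotation is None:
        return base

    mult_by_gene = {
        r["gene_id"]: config.gene_class_rho_mult[r["true_cpg_class"]]
        for _, r in gene_truth.iterrows()
    }
    cds = annotation[annotation["element"] == "CDS"]
    out_rows = []
    for chrom, chrom_base in base.groupby("chrom", sort=True):
        cuts = set(chrom_base["start"]) | set(chrom_base["end"])
        chrom_cds = cds[cds["chrom"] == chrom]
        cuts |= set(chrom_cds["start"]) | set(chrom_cds["end"])
        cuts = np.array(sorted(cuts))
        starts_b = chrom_base["start"].to_numpy()
        rho_b = chrom_base["rho_per_kb"].to_numpy()
        cds_starts = chrom_cds["start"].to_numpy()
        cds_ends = chrom_cds["end"].to_numpy()
        cds_mult = np.array(
            [mult_by_gene[g] for g in chrom_cds["gene_id"]], dtype=float
        )
        order = np.argsort(cds_starts)
        cds_starts, cds_ends, cds_mult = (
            cds_starts[order],
            cds_ends[order],
            cds_mult[order],
        )
        for s, e in zip(cuts[:-1], cuts[1:]):
            rho = rho_b[np.searchsorted(starts_b, s, side="right") - 1]
            j = np.searchsorted(cds_starts, s, side="right") - 1
            if j >= 0 and cds_ends[j] > s:
                rho *= cds_mult[j]
            out_rows.append(
                {"chrom": chrom, "start": int(s), "end": int(e), "rho_per_kb": rho}
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# SNPs, outgroup and truth


def _sample_frequencies(
    m: int, B: float, n: int, rng: np.random.Generator, grid_size: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """Draw m (x, k) pairs: population frequency x from the normalized
    sojourn density phi(x; B) on a fine grid, sample count k binomial,
    jointly rejected until segregating (0 < k < n)."""
    grid = (np.arange(grid_size) + 0.5) / grid_size
    dens = sojourn_density(grid, B)
    prob = dens / dens.sum()
    xs = np.empty(m)
    ks = np.empty(m, dtype=int)
    todo = np.arange(m)
    while todo.size:
        x_new = rng.choice(grid, size=todo.size, p=prob)
        k_new = rng.binomial(n, x_new)
        xs[todo] = x_new
        ks[todo] = k_new
        todo = todo[(k_new == 0) | (k_new == n)]
    return xs, ks


def _mutate_outgroup(
    codes: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Evolve base-index codes along the outgroup branch (one hit max per
    site; branch lengths here are short enough for that to be adequate)."""
    out = codes.copy()
    hit = rng.random(len(codes)) < config.outgroup_branch
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return out
    u = rng.random(idx.size)
    is_ti = u < config.outgroup_ti_fraction
    cur = out[idx]
    new = np.empty(idx.size, dtype=np.int8)
    new[is_ti] = np.array([_TI[c] for c in cur[is_ti]], dtype=np.int8)
    # transversions: pick between the two partners of the other pairing
    tv_choice = rng.integers(0, 2, size=idx.size)
    tv_partners = {
        0: (1, 3), 2: (1, 3),  # A,G -> C or T
        1: (0, 2), 3: (0, 2),  # C,T -> A or G
    }
    for j in np.flatnonzero(~is_ti):
        new[j] = tv_partners[int(cur[j])][tv_choice[j]]
    out[idx] = new
    return out


def _coverage_mask(
    length: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean outgroup-coverage mask with exponential-length gaps."""
    mask = np.ones(length, dtype=bool)
    target_uncovered = length * (1 - config.outgroup_coverage)
    uncovered = 0.0
    while uncovered < target_uncovered:
        gap = max(50, int(rng.exponential(config.outgroup_gap_len)))
        start = int(rng.integers(0, max(length - gap, 1)))
        mask[start : start + gap] = False
        uncovered += gap
    return mask


def simulate_snps(
    config: SimConfig,
    reference: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, np.ndarray], pd.DataFrame]:
    """Simulate segregating sites, the outgroup consensus and ground truth.

    Per mutation class the site count is Poisson(theta_class x eligible
    bases), with W (A/T) bases eligible for WS and WW mutations and S
    (G/C) bases for SW and SS.  The ancestral allele is the local
    reference base; the derived allele follows the AT bias lambda and the
    Ti/Tv mix; the derived population frequency is drawn from the sojourn
    density with the class's planted B (B_ti for WS/SW transitions, B_tv
    for transversions, mirrored negative for SW, 0 for WW/SS).  The
    outgroup consensus is the reference evolved along ``outgroup_branch``
    (double hits with the ingroup create mispolarization pressure).

    Returns ``(variants, outgroup, coverage_mask, snp_truth)``; variants
    is a table with 1-based positions, ref/alt (= ancestral/derived),
    derived sample count k, and per-site outgroup allele and depth.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_haplotypes
    var_rows = []
    truth_rows = []
    outgroup: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    for chrom in sorted(reference):
        seq = reference[chrom]
        codes = np.frombuffer(seq.encode(), dtype="S1")
        codes = np.searchsorted(np.sort(base_arr), codes).astype(np.int8)
        # np.sort(base_arr) == A,C,G,T already; codes now index into BASES
        w_pos = np.flatnonzero((codes == 0) | (codes == 3))
        s_pos = np.flatnonzero((codes == 1) | (codes == 2))

        # expected segregating-site counts: mutational influx times the
        # relative mean sojourn of the class's bias (normalized so B = 0
        # reproduces the plain theta * eligible-bases intensity)
        g0 = expected_class_spectrum(0.0, n).sum()

        def sojourn(b: float) -> float:
            return float(expected_class_spectrum(b, n).sum() / g0)

        ti_f = config.ti_fraction
        ws_rate = config.theta_ws * (
            ti_f * sojourn(config.B_ti) + (1 - ti_f) * sojourn(config.B_tv)
        )
        sw_rate = (
            config.lam
            * config.theta_ws
            * (ti_f * sojourn(-config.B_ti) + (1 - ti_f) * sojourn(-config.B_tv))
        )
        n_ws = int(rng.poisson(ws_rate * w_pos.size))
        n_ww = int(rng.poisson(config.theta_ww * w_pos.size))
        n_sw = int(rng.poisson(sw_rate * s_pos.size))
        n_ss = int(rng.poisson(config.theta_ss * s_pos.size))
        # Ti fraction among observed (segregating) sites, tilted by sojourn
        ti_p = {
            "WS": ti_f
            * sojourn(config.B_ti)
            / (ti_f * sojourn(config.B_ti) + (1 - ti_f) * sojourn(config.B_tv)),
            "SW": ti_f
            * sojourn(-config.B_ti)
            / (ti_f * sojourn(-config.B_ti) + (1 - ti_f) * sojourn(-config.B_tv)),
        }
        w_take = min(n_ws + n_ww, w_pos.size)
        s_take = min(n_sw + n_ss, s_pos.size)
        w_sites = rng.choice(w_pos, size=w_take, replace=False)
        s_sites = rng.choice(s_pos, size=s_take, replace=False)
        site_class = [
            (w_sites[:n_ws], "WS"),
            (w_sites[n_ws:], "WW"),
            (s_sites[:n_sw], "SW"),
            (s_sites[n_sw:], "SS"),
        ]

        out_codes = _mutate_outgroup(codes, config, rng)
        mask = _coverage_mask(len(seq), config, rng)
        outgroup[chrom] = base_arr[out_codes].tobytes().decode()
        masks[chrom] = mask

        # derived alleles, planted B and frequencies, batched per class
        ti_tv_ws = {0: 1, 3: 2}  # A->C, T->G (the one WS transversion per W base)
        ti_tv_sw = {1: 0, 2: 3}  # C->A, G->T
        for positions, mclass in site_class:
            m = positions.size
            if m == 0:
                continue
            anc = codes[positions].astype(int)
            if mclass in ("WS", "SW"):
                is_ti = rng.random(m) < ti_p[mclass]
                tv_map = ti_tv_ws if mclass == "WS" else ti_tv_sw
                der = np.where(
                    is_ti,
                    [_TI[a] for a in anc],
                    [tv_map[a] for a in anc],
                )
                sign = 1.0 if mclass == "WS" else -1.0
                b_site = sign * np.where(is_ti, config.B_ti, config.B_tv)
            else:
                der = 3 - anc  # A<->T or C<->G
                b_site = np.zeros(m)
            xs = np.empty(m)
            ks = np.empty(m, dtype=int)
            for b_val in np.unique(b_site):
                sel = b_site == b_val
                xs[sel], ks[sel] = _sample_frequencies(
                    int(sel.sum()), float(b_val), n, rng
                )
            for j in range(m):
                p = int(positions[j])
                a, d = int(anc[j]), int(der[j])
                out_allele = BASES[out_codes[p]]
                var_rows.append(
                    {
                        "chrom": chrom,
                        "pos": p + 1,
                        "ref": BASES[a],
                        "alt": BASES[d],
                        "k": int(ks[j]),
                        "n": n,
                        "outgroup_allele": out_allele,
                        "outgroup_depth": (
                            config.outgroup_covered_depth if mask[p] else 0
                        ),
                        "left_base": seq[p - 1] if p > 0 else None,
                        "right_base": seq[p + 1] if p + 1 < len(seq) else None,
                    }
                )
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "pos": p + 1,
                        "ancestral": BASES[a],
                        "derived": BASES[d],
                        "mclass": mclass,
                        "titv": "Ti" if _TI[a] == d else "Tv",
                        "x_true": float(xs[j]),
                        "k": int(ks[j]),
                        "B_true": float(b_site[j]),
                        "outgroup_allele": out_allele,
                        "mispolarized": out_allele != BASES[a],
                    }
                )
    variants = pd.DataFrame(var_rows).sort_values(["chrom", "pos"]).reset_index(
        drop=True
    )
    snp_truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(
        drop=True
    )
    return variants, outgroup, masks, snp_truth


def simulate_class_sfs(
    B: float,
    n: int,
    theta_ws: float,
    theta_sw: float | None = None,
    theta_n: float | None = None,
    lam: float | None = None,
    gc: float = 0.34,
    r: np.ndarray | None = None,
    e_ws: float = 0.0,
    e_sw: float = 0.0,
    e_n: float = 0.0,
    seed: int = 0,
) -> ClassSFS:
    """Poisson draws around the expected observed class spectra.

    The fast path for estimator testing: no genome, just seeded counts.
    ``theta_sw`` defaults to the value implied by ``lam`` and ``gc``
    (theta_SW = lam * theta_WS * gc / (1 - gc)); ``theta_n`` defaults to
    ``theta_ws``.  Bit-reproducible given ``seed``.
    """
    if theta_sw is None:
        if lam is None:
            raise ValueError("provide theta_sw or lam")
        theta_sw = lam * theta_ws * gc / (1.0 - gc)
    if theta_n is None:
        theta_n = theta_ws
    params = GbgcFit(
        B=B,
        theta_ws=theta_ws,
        theta_sw=theta_sw,
        theta_n=theta_n,
        e_ws=e_ws,
        e_sw=e_sw,
        e_n=e_n,
        r=r,
    )
    expected = expected_observed_spectra(params, n)
    rng = np.random.default_rng(seed)
    return ClassSFS(
        n=n,
        counts_ws=rng.poisson(expected["WS"]).astype(float),
        counts_sw=rng.poisson(expected["SW"]).astype(float),
        counts_n=rng.poisson(expected["N"]).astype(float),
    )


# ---------------------------------------------------------------------------
# gene tables


def simulate_gene_tables(
    config: SimConfig,
    gene_truth: pd.DataFrame,
    annotation: pd.DataFrame,
    reference: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, list[str]]], pd.DataFrame, pd.DataFrame]:
    """Caste-expression gene lists and a methylated-CpG site table.

    Methylation is planted per gene: an LCpG gene is methylated with the
    configured probability (and at a higher per-CpG level) than an HCpG
    gene.  Expression classes are drawn either from a CpG-class-dependent
    distribution (with probability ``expr_assoc``) or independently, so
    an association strength of 0 makes expression independent of CpG
    class.

    Returns ``(expression_lists, mcpg_table, gene_table_truth)``.
    """
    rng = config.rng() if rng is None else rng
    cds = annotation[annotation["element"] == "CDS"]
    expr_lists: dict[str, dict[str, list[str]]] = {
        "qw": {"QgtW": [], "WgtQ": [], "NS": []},
        "dw": {"DgtW": [], "WgtD": [], "NS": []},
    }
    # class-conditional expression tendencies (female-biased genes are HCpG)
    qw_probs = {
        "HCpG": (0.25, 0.25, 0.5),
        "LCpG": (0.05, 0.05, 0.9),
        "base": (0.1, 0.1, 0.8),
    }
    dw_probs = {
        "HCpG": (0.05, 0.40, 0.55),
        "LCpG": (0.35, 0.05, 0.6),
        "base": (0.15, 0.15, 0.7),
    }
    mcpg_rows = []
    truth_rows = []
    for _, g in gene_truth.iterrows():
        cls = g["true_cpg_class"]
        use_assoc = rng.random() < config.expr_assoc
        pq = qw_probs[cls if use_assoc else "base"]
        pdw = dw_probs[cls if use_assoc else "base"]
        expr_q = rng.choice(["QgtW", "WgtQ", "NS"], p=pq)
        expr_d = rng.choice(["DgtW", "WgtD", "NS"], p=pdw)
        expr_lists["qw"][expr_q].append(g["gene_id"])
        expr_lists["dw"][expr_d].append(g["gene_id"])

        methylated = rng.random() < config.meth_prob[cls]
        level = config.meth_level[cls] if methylated else 0.0
        n_mcpg = 0
        if methylated:
            seq = reference[g["chrom"]]
            gene_cds = cds[cds["gene_id"] == g["gene_id"]]
            for _, row in gene_cds.iterrows():
                for p in range(int(row["start"]), int(row["end"])):
                    if seq[p : p + 2].upper() == "CG" and rng.random() < level:
                        mcpg_rows.append(
                            {
                                "chrom": g["chrom"],
                                "pos": p,  # 0-based C coordinate
                                "gene_id": g["gene_id"],
                            }
                        )
                        n_mcpg += 1
        truth_rows.append(
            {
                "gene_id": g["gene_id"],
                "true_cpg_class": cls,
                "true_expr_qw": expr_q,
                "true_expr_dw": expr_d,
                "true_methylated": methylated and n_mcpg > 0,
                "true_meth_level": level,
                "n_mcpg": n_mcpg,
            }
        )
    mcpg = pd.DataFrame(mcpg_rows, columns=["chrom", "pos", "gene_id"])
    return expr_lists, mcpg, pd.DataFrame(truth_rows)


def simulate_run(config: SimConfig) -> dict:
    """Run the full generator: genome, rho map, SNPs, gene tables, truth.

    Returns a dict with keys reference, annotation, rho_map, variants,
    outgroup, coverage, expression_lists, mcpg, truth (a TruthTable).
    Deterministic: one seeded generator drives every step in order.
    """
    rng = config.rng()
    reference, annotation, gene_truth = simulate_genome(config, rng)
    rho_map = simulate_rho_map(config, gene_truth, annotation, rng)
    variants, outgroup, coverage, snp_truth = simulate_snps(config, reference, rng)
    expr_lists, mcpg, gene_table_truth = simulate_gene_tables(
        config, gene_truth, annotation, reference, rng
    )
    genes_full = gene_truth.merge(
        gene_table_truth.drop(columns=["true_cpg_class"]), on="gene_id"
    )
    regions = rho_map.copy()
    regions["B_ti"] = config.B_ti
    regions["B_tv"] = config.B_tv
    regions["lambda"] = config.lam
    return {
        "config": config,
        "reference": reference,
        "annotation": annotation,
        "rho_map": rho_map,
        "variants": variants,
        "outgroup": outgroup,
        "coverage": coverage,
        "expression_lists": expr_lists,
        "mcpg": mcpg,
        "truth": TruthTable(snps=snp_truth, regions=regions, genes=genes_full),
    }
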