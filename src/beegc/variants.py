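"""Biallelic SNP polarization, mutation classification and site filters.

Ancestral/derived states are assigned with a substitution-aware weighted
parsimony rule: for an ingroup polymorphism {X, Y} with outgroup allele O,
the two polarization scenarios are weighted by the probability of the
mutation that created the polymorphism (an ingroup mutation-weight matrix
``mu``) times the probability of any outgroup-lineage substitution needed
to reconcile O with the assumed ancestral allele (a substitution matrix
``sigma``).  Simple parsimony is the ``sigma = 0`` limit.

Mutations are classified by weak/strong membership of the ancestral and
derived alleles (W = A/T, S = G/C -> WS, SW, WW, SS), by transition vs
transversion, and by whether the derived or ancestral allele creates or
destroys a CpG or GpC dinucleotide in its reference flanking context.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
WEAK = frozenset("AT")
STRONG = frozenset("GC")
PURINES = frozenset("AG")

#: dinucleotide-context flags
CPG_CREATING = "CpG-creating"
GPC_CREATING = "GpC-creating"
CPG_DESTROYING = "CpG-destroying"
GPC_DESTROYING = "GpC-destroying"


@dataclass(frozen=True)
class SiteAlleles:
    """One biallelic ingroup site with optional outgroup information.

    ``pos`` is 1-based (VCF convention); ``count_y`` is the number of
    copies of ``allele_y`` among the ``n`` sampled haplotypes and must be
    strictly between 0 and ``n`` (the site is segregating).
    """

    chrom: str
    pos: int
    allele_x: str
    allele_y: str
    count_y: int
    n: int = 60
    outgroup_allele: str | None = None
    outgroup_depth: int = 0
    left_base: str | None = None
    right_base: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.allele_x == self.allele_y:
            raise ValueError("allele_x and allele_y must differ")
        for a in (self.allele_x, self.allele_y):
            if a not in BASE_INDEX:
                raise ValueError(f"invalid allele {a!r}")
        if not 0 < self.count_y < self.n:
            raise ValueError(
                f"count_y must satisfy 0 < count_y < n, got {self.count_y}/{self.n}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A raw variant as read from a VCF, before biallelic-SNP filtering."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    alt_count: int
    n: int
    outgroup_allele: str | None = None
    outgroup_depth: int = 0
    left_base: str | None = None
    right_base: str | None = None

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref in BASE_INDEX
            and self.alts[0] in BASE_INDEX
        )

    def to_site(self) -> SiteAlleles:
        if not self.is_biallelic_snp:
            raise ValueError(f"{self.chrom}:{self.pos} is not a biallelic SNP")
        return SiteAlleles(
            chrom=self.chrom,
            pos=self.pos,
            allele_x=self.ref,
            allele_y=self.alts[0],
            count_y=self.alt_count,
            n=self.n,
            outgroup_allele=self.outgroup_allele,
            outgroup_depth=self.outgroup_depth,
            left_base=self.left_base,
            right_base=self.right_base,
        )


@dataclass
class SubstitutionModel:
    """Per-site mutation weights (ingroup) and substitution probabilities
    (outgroup lineage) for all 12 ordered base pairs.

    ``mu[x, y]`` is the per-X-site rate at which X -> Y polymorphisms
    arise in the ingroup; ``sigma[x, y]`` the per-X-site probability of a
    fixed X -> Y substitution on the outgroup lineage.  Diagonals are 0.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        for name, m in (("mu", self.mu), ("sigma", self.sigma)):
            if m.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4")
            if (m < 0).any():
                raise ValueError(f"{name} entries must be >= 0")
            if np.diag(m).any():
                raise ValueError(f"{name} diagonal must be 0")
        if (self.sigma.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("sigma rows must sum to <= 1")


@dataclass(frozen=True)
class PolarizedSNP:
    """A polarized biallelic SNP with mutation-class annotations."""

    site: SiteAlleles
    ancestral: str
    derived: str
    p_ancestral: float
    k: int
    mclass: str
    titv: str
    context: frozenset = field(default_factory=frozenset)

    @property
    def f_d(self) -> float:
        """Derived allele frequency k/n in the sample."""
        return self.k / self.site.n


@dataclass(frozen=True)
class Unresolved:
    """A site whose ancestral state could not be assigned."""

    site: SiteAlleles
    reason: str


def classify_mutation(ancestral: str, derived: str) -> tuple[str, str]:
    """Classify an ancestral -> derived change by W/S membership and Ti/Tv.

    Returns ``(mclass, titv)`` with mclass in {WS, SW, WW, SS} and titv in
    {Ti, Tv}.  Transitions are A<->G and C<->T.
    """
    if ancestral not in BASE_INDEX or derived not in BASE_INDEX:
        raise ValueError(f"alleles must be in ACGT, got {ancestral!r}->{derived!r}")
    if ancestral == derived:
        raise ValueError("ancestral and derived alleles are identical")
    a_weak = ancestral in WEAK
    d_weak = derived in WEAK
    mclass = ("W" if a_weak else "S") + ("W" if d_weak else "S")
    titv = "Ti" if (ancestral in PURINES) == (derived in PURINES) else "Tv"
    return mclass, titv


def dinucleotide_context(
    left: str | None, right: str | None, ancestral: str, derived: str
) -> frozenset:
    """CpG/GpC creation and destruction flags for a polarized change.

    The derived allele *creates* a CpG when it completes a CG dinucleotide
    that the ancestral allele did not form (derived G after a C, or derived
    C before a G); GpC analogously.  Destruction is the symmetric statement
    about the ancestral allele.  Missing flanks contribute no flags.
    """
    flags = set()

    def forms(dinuc: str, base: str) -> bool:
        # does `base` at the focal position complete `dinuc` with a flank?
        return (left == dinuc[0] and base == dinuc[1]) or (
            base == dinuc[0] and right == dinuc[1]
        )

    for dinuc, create_flag, destroy_flag in (
        ("CG", CPG_CREATING, CPG_DESTROYING),
        ("GC", GPC_CREATING, GPC_DESTROYING),
    ):
        if forms(dinuc, derived) and not forms(dinuc, ancestral):
            flags.add(create_flag)
        if forms(dinuc, ancestral) and not forms(dinuc, derived):
            flags.add(destroy_flag)
    return frozenset(flags)


def estimate_substitution_model(
    sites: Iterable[SiteAlleles],
    fixed_differences: Mapping[tuple[str, str], int] | np.ndarray,
    class_totals: Mapping[str, int] | Sequence[int],
) -> SubstitutionModel:
    """Estimate mu and sigma from polymorphism and fixed-difference counts.

    ``mu[x, y]`` = (# polymorphisms with outgroup allele X and alleles
    {X, Y}) / (# aligned X bases); ``sigma[x, y]`` = (# sites fixed for X
    in the ingroup where the outgroup shows Y) / (# aligned X bases).
    Both are per-site rates on the same opportunity scale.
    """
    if isinstance(class_totals, Mapping):
        totals = np.array([float(class_totals[b]) for b in BASES])
    else:
        totals = np.asarray(class_totals, dtype=float)
    if (totals < 0).any():
        raise ValueError("base composition counts must be >= 0")
    for b, t in zip(BASES, totals):
        if t == 0:
            raise ValueError(f"zero opportunity count for base {b}")

    if isinstance(fixed_differences, np.ndarray):
        fixed = np.asarray(fixed_differences, dtype=float)
    else:
        fixed = np.zeros((4, 4))
        for (x, y), c in fixed_differences.items():
            fixed[BASE_INDEX[x], BASE_INDEX[y]] = c
    if (fixed < 0).any():
        raise ValueError("fixed-difference counts must be >= 0")

    poly = np.zeros((4, 4))
    for s in sites:
        o = s.outgroup_allele
        if o is None or o not in BASE_INDEX:
            continue
        if o == s.allele_x:
            poly[BASE_INDEX[o], BASE_INDEX[s.allele_y]] += 1
        elif o == s.allele_y:
            poly[BASE_INDEX[o], BASE_INDEX[s.allele_x]] += 1
        # outgroup allele not among the ingroup alleles: uninformative for mu

    mu = poly / totals[:, None]
    sigma = fixed / totals[:, None]
    np.fill_diagonal(mu, 0.0)
    np.fill_diagonal(sigma, 0.0)
    return SubstitutionModel(mu=mu, sigma=sigma)


def count_fixed_differences(
    reference: Mapping[str, str],
    outgroup: Mapping[str, str],
    coverage: Mapping[str, np.ndarray] | None = None,
    exclude_positions: Mapping[str, Iterable[int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed ingroup/outgroup differences and aligned base composition.

    Compares the ingroup reference with the outgroup consensus at covered
    positions (per-chromosome boolean masks), excluding ingroup-polymorphic
    positions (0-based).  Returns ``(fixed, totals)``: a 4x4 ordered-pair
    count matrix (reference base -> outgroup base) and the aligned count
    of each reference base, both suitable for
    :func:`estimate_substitution_model`.
    """
    fixed = np.zeros((4, 4))
    totals = np.zeros(4)
    order = np.frombuffer(BASES.encode(), dtype="S1")
    for chrom in reference:
        ref = np.frombuffer(reference[chrom].upper().encode(), dtype="S1")
        out = np.frombuffer(outgroup[chrom].upper().encode(), dtype="S1")
        ok = np.isin(ref, order) & np.isin(out, order)
        if coverage is not None:
            ok &= np.asarray(coverage[chrom], dtype=bool)
        if exclude_positions is not None and chrom in exclude_positions:
            excl = np.fromiter(exclude_positions[chrom], dtype=int)
            keep = np.ones(len(ref), dtype=bool)
            keep[excl] = False
            ok &= keep
        ref_i = np.searchsorted(order, ref[ok])
        out_i = np.searchsorted(order, out[ok])
        np.add.at(totals, ref_i, 1)
        np.add.at(fixed, (ref_i, out_i), 1)
    np.fill_diagonal(fixed, 0.0)
    return fixed, totals


def polarize_site(
    site: SiteAlleles,
    model: SubstitutionModel,
    p_threshold: float = 0.9,
    min_outgroup_depth: int = 5,
) -> PolarizedSNP | Unresolved:
    """Assign ancestral/derived states by substitution-aware weighted parsimony.

    With ingroup alleles {X, Y} and outgroup allele O:

    * O == X: weight(anc=X) = mu(X->Y); weight(anc=Y) = mu(Y->X)*sigma(Y->X)
      (the outgroup must have substituted back to X);
    * O not in {X, Y}: weight(anc=X) = mu(X->Y)*sigma(X->O) and
      weight(anc=Y) = mu(Y->X)*sigma(Y->O).

    The larger-weight scenario is chosen with confidence
    ``p_ancestral = w_best / (w_x + w_y)``; ties and
    ``p_ancestral < p_threshold`` are returned :class:`Unresolved`.
    """
    o = site.outgroup_allele
    if o is None or o not in BASE_INDEX or site.outgroup_depth < min_outgroup_depth:
        return Unresolved(site, "no outgroup")
    x, y = site.allele_x, site.allele_y
    xi, yi, oi = BASE_INDEX[x], BASE_INDEX[y], BASE_INDEX[o]
    mu, sigma = model.mu, model.sigma
    if o == x:
        w_x = mu[xi, yi]
        w_y = mu[yi, xi] * sigma[yi, xi]
    elif o == y:
        w_y = mu[yi, xi]
        w_x = mu[xi, yi] * sigma[xi, yi]
    else:
        w_x = mu[xi, yi] * sigma[xi, oi]
        w_y = mu[yi, xi] * sigma[yi, oi]

    total = w_x + w_y
    if total == 0:
        return Unresolved(site, "uninformative model")
    if w_x == w_y:
        return Unresolved(site, "tie")
    if w_x > w_y:
        ancestral, derived, k = x, y, site.count_y
    else:
        ancestral, derived, k = y, x, site.n - site.count_y
    p = max(w_x, w_y) / total
    if p < p_threshold:
        return Unresolved(site, "below threshold")
    mclass, titv = classify_mutation(ancestral, derived)
    context = dinucleotide_context(site.left_base, site.right_base, ancestral, derived)
    return PolarizedSNP(
        site=site,
        ancestral=ancestral,
        derived=derived,
        p_ancestral=p,
        k=k,
        mclass=mclass,
        titv=titv,
        context=context,
    )


def polarize_sites(
    sites: Iterable[SiteAlleles],
    model: SubstitutionModel,
    p_threshold: float = 0.9,
    min_outgroup_depth: int = 5,
) -> tuple[list[PolarizedSNP], list[Unresolved]]:
    """Polarize a collection of sites, separating resolved and unresolved."""
    resolved: list[PolarizedSNP] = []
    unresolved: list[Unresolved] = []
    for site in sites:
        out = polarize_site(site, model, p_threshold, min_outgroup_depth)
        (resolved if isinstance(out, PolarizedSNP) else unresolved).append(out)
    return resolved, unresolved


def filter_sites(
    sites: Iterable[SiteAlleles | VariantRecord],
    min_outgroup_depth: int = 5,
    biallelic_only: bool = True,
) -> tuple[list, Counter]:
    """Retain biallelic SNPs with sufficient outgroup coverage.

    Returns the retained sites together with a counter of removal reasons
    (``not_biallelic``, ``low_outgroup_depth``).
    """
    kept: list = []
    removed: Counter = Counter()
    for s in sites:
        if biallelic_only and isinstance(s, VariantRecord) and not s.is_biallelic_snp:
            removed["not_biallelic"] += 1
            continue
        if s.outgroup_depth < min_outgroup_depth:
            removed["low_outgroup_depth"] += 1
            continue
        kept.append(s)
    return kept, removed


def maf_prune(sites: Sequence[SiteAlleles], maf_threshold: float) -> list[SiteAlleles]:
    """Remove sites with minor allele frequency below ``maf_threshold``.

    A site is kept when min(count_y, n - count_y)/n >= threshold (the
    boundary frequency is retained).
    """
    if not 0 <= maf_threshold < 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5)")
    return [
        s
        for s in sites
        if min(s.count_y, s.n - s.count_y) / s.n >= maf_threshold
    ]


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1..n} 1/i (Watterson's denominator uses a_{n-1})."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def cap_element_diversity(
    grouped_sites: Mapping[str, tuple[Sequence, int]],
    theta_cap: float,
    seed: int,
) -> dict[str, list]:
    """Cap per-element Watterson diversity by uniform SNP subsampling.

    ``grouped_sites`` maps an element id to ``(sites, L)`` where ``L`` is
    the element length in bases.  For every element whose theta_w =
    S / (a_{n-1} * L) exceeds ``theta_cap``, the largest SNP subset whose
    theta_w is at or below the cap is drawn uniformly without replacement.
    Deterministic given ``seed``.
    """
    if theta_cap <= 0:
        raise ValueError("theta_cap must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for element_id in sorted(grouped_sites):
        sites, length = grouped_sites[element_id]
        sites = list(sites)
        if not sites:
            out[element_id] = sites
            continue
        n = sites[0].n
        denom = harmonic_number(n - 1) * length
        if len(sites) / denom <= theta_cap:
            out[element_id] = sites
            continue
        s_max = int(math.floor(theta_cap * denom))
        idx = rng.choice(len(sites), size=s_max, replace=False)
        out[element_id] = [sites[i] for i in sorted(idx)]
    return out
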