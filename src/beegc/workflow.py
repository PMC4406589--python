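"""High-level composition of the polarization pipeline.

Glues the per-step operations together for callers that have a full
dataset in memory (reference, outgroup consensus with coverage mask, and
variant records): substitution-model estimation from the data itself,
then weighted-parsimony polarization of every eligible site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from beegc import io, variants


@dataclass
class PolarizationResult:
    resolved: list
    unresolved: list
    model: variants.SubstitutionModel
    removed: Counter


def polarize_dataset(
    reference: Mapping[str, str],
    outgroup: Mapping[str, str],
    coverage: Mapping[str, np.ndarray] | None,
    records: Sequence[variants.VariantRecord],
    p_threshold: float = 0.9,
    min_outgroup_depth: int = 5,
) -> PolarizationResult:
    """Estimate the substitution model and polarize a variant dataset.

    The ingroup mutation-weight matrix comes from the polymorphism counts
    of the eligible sites themselves; the outgroup substitution matrix
    from ingroup/outgroup fixed differences at covered non-polymorphic
    positions.  Sites failing the biallelic or coverage filters are
    counted, not errors.
    """
    sites = io.annotate_sites(records, reference, outgroup, coverage)
    kept, removed = variants.filter_sites(
        sites, min_outgroup_depth=min_outgroup_depth
    )
    snp_positions: dict[str, list[int]] = {}
    for s in sites:
        snp_positions.setdefault(s.chrom, []).append(s.pos - 1)
    fixed, totals = variants.count_fixed_differences(
        reference, outgroup, coverage, snp_positions
    )
    model = variants.estimate_substitution_model(kept, fixed, totals)
    resolved, unresolved = variants.polarize_sites(
        kept, model, p_threshold=p_threshold, min_outgroup_depth=min_outgroup_depth
    )
    return PolarizationResult(
        resolved=resolved, unresolved=unresolved, model=model, removed=removed
    )


def records_from_frame(variants_df) -> list[variants.VariantRecord]:
    """Variant records from a generator variants table (chrom, pos, ref,
    alt, k, n columns)."""
    return [
        variants.VariantRecord(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alts=(r.alt,),
            alt_count=int(r.k),
            n=int(r.n),
        )
        for r in variants_df.itertuples()
    ]
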