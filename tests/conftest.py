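import numpy as np
import pytest

from beegc import simulate, workflow


def make_site(k=10, n=60, x="A", y="G", out=None, depth=20, left=None, right=None,
              chrom="chr1", pos=100):
    from beegc.variants import SiteAlleles

    return SiteAlleles(
        chrom=chrom, pos=pos, allele_x=x, allele_y=y, count_y=k, n=n,
        outgroup_allele=out, outgroup_depth=depth, left_base=left, right_base=right,
    )


@pytest.fixture(scope="session")
def small_run():
    """A 300 kb synthetic run at study-like settings (shared, read-only)."""
    config = simulate.SimConfig(
        seed=5, chrom_lengths={"chr1": 300_000}, theta_ws=0.008
    )
    return simulate.simulate_run(config)


@pytest.fixture(scope="session")
def small_polarized(small_run):
    """Weighted-parsimony polarization of the shared small run."""
    records = workflow.records_from_frame(small_run["variants"])
    return workflow.polarize_dataset(
        small_run["reference"],
        small_run["outgroup"],
        small_run["coverage"],
        records,
    )
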