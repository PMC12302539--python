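import numpy as np
import pytest

from velscan.enhancer_catalog import EnhancerCatalog, quantify_rpkm
from velscan.genomic_core import GenomicInterval, IntervalSet
from velscan.synthetic_cohort import CohortConfig, PlantSpec, simulate_cohort


def catalog_from_loci(loci) -> EnhancerCatalog:
    """Wrap pre-placed loci (already ids E..., non-overlapping) as a catalog."""
    return EnhancerCatalog(loci=IntervalSet(loci))


def signal_from_bundle(bundle):
    cat = catalog_from_loci(bundle.catalog_intervals)
    sig = quantify_rpkm(
        bundle.counts.loc[cat.locus_ids], cat.lengths(), bundle.library_sizes
    )
    return cat, sig


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(
        n_pairs=4,
        n_enhancers=120,
        n_genes=40,
        genome=(("chr1", 3_000_000), ("chr2", 2_000_000)),
        planted=(
            PlantSpec("gain", n_loci=10, recurrence_design=3),
            PlantSpec("lost", n_loci=10, recurrence_design=3),
        ),
        library_size_range=(1_000_000, 2_000_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def reference_config():
    """The reference study design: 20 pairs, 5000 enhancers, 200+200 planted."""
    return CohortConfig(seed=7)


@pytest.fixture(scope="session")
def reference_bundle(reference_config):
    return simulate_cohort(reference_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
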