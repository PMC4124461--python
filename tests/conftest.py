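import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from fxpoi.variants import AnnotatedVariant, Consequence, Genotype, SampleDesign

CASES = ("poi1", "poi2", "poi3", "poi4", "poi5")
CONTROLS = ("ctr6", "ctr7", "ctr8", "ctr9", "ctr10")


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return SampleDesign(case_ids=frozenset(CASES), control_ids=frozenset(CONTROLS))


def make_variant(
    pos=101,
    *,
    chrom="1",
    ref="A",
    alt="G",
    quality=50.0,
    qd=10.0,
    hrun=2,
    sb=-0.5,
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    carriers=(),
    no_calls=(),
    dbsnp_known=True,
    mafs=None,
    deleteriousness=None,
) -> AnnotatedVariant:
    """Variant builder with passing quality and fully called genotypes."""
    genotypes = {}
    for s in CASES + CONTROLS:
        if s in no_calls:
            genotypes[s] = Genotype.NO_CALL
        elif s in carriers:
            genotypes[s] = Genotype.HET
        else:
            genotypes[s] = Genotype.HOM_REF
    return AnnotatedVariant(
        chromosome=chrom,
        position=pos,
        ref=ref,
        alt=alt,
        site_quality=quality,
        quality_by_depth=qd,
        homopolymer_run=hrun,
        strand_bias=sb,
        genotypes=genotypes,
        gene=gene,
        consequence=consequence,
        dbsnp_known=dbsnp_known,
        maf_sources=mafs or {},
        deleteriousness_call=deleteriousness,
    )


@pytest.fixture(scope="session")
def variant_table_dir(tmp_path_factory):
    """Default synthetic variant-table artifacts on disk, generated once."""
    from fxpoi.simulate import VariantGeneratorConfig, generate_variant_table

    outdir = tmp_path_factory.mktemp("variant_table")
    config = VariantGeneratorConfig()
    truth = generate_variant_table(config, seed=41, outdir=outdir)
    return outdir, config, truth


@pytest.fixture(scope="session")
def random_variant_pool(design):
    """1000 random fully-called non-synonymous variants over 60 genes,
    used for the enrichment recount oracle and filter-invariant checks."""
    rng = np.random.default_rng(12345)
    samples = list(design.all_ids)
    pool = []
    for i in range(1000):
        carriers = tuple(
            s for s in samples if rng.random() < 0.25
        )
        pool.append(
            make_variant(
                pos=1000 + i,
                gene=f"G{rng.integers(0, 60):02d}",
                carriers=carriers,
                consequence=Consequence.MISSENSE
                if rng.random() < 0.8
                else Consequence.STOP_GAIN,
            )
        )
    return pool
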