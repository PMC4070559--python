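import pytest

from vdjwin import (
    GermlineDB,
    GermlineGene,
    KmerIndex,
    RunConfig,
    Seed,
    SimParams,
    run_pipeline,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def toy_db():
    """Tiny VJ germline with a contiguous k=4 seed, small enough that
    every index entry can be enumerated by hand or brute force."""
    return GermlineDB(
        locus="TOY",
        v_genes=[GermlineGene("toyV", "AAACCC", "V")],
        j_genes=[GermlineGene("toyJ", "ACCCGG", "J")],
        seed=Seed.contiguous(4),
    )


@pytest.fixture(scope="session")
def toy_index(toy_db):
    return KmerIndex.build(toy_db)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free amplicon dataset from a TRG-like synthetic germline."""
    params = SimParams(rng_seed=11, n_clones=5, n_reads=400)
    return params, *simulate_dataset(params)


@pytest.fixture(scope="session")
def clean_report(clean_sim):
    params, db, clones, reads, truths = clean_sim
    return run_pipeline(RunConfig(db=db), reads)
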