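import random

import pytest

from selenoscan.pipeline import predict_species
from selenoscan.refdb import Parameters, build_scoring_matrix
from selenoscan.simgen import SyntheticCohortSpec, generate_cohort, make_reference_db


@pytest.fixture(scope="session")
def matrix():
    return build_scoring_matrix()


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def ref_db():
    return make_reference_db(seed=0)


@pytest.fixture()
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One-species cohort exercising every planted structure, kept small."""
    spec = SyntheticCohortSpec(
        n_species=1, contigs_per_species=2, contig_length_nt=120_000,
        n_sec_genes=8, n_cys_homologs=5, n_other_homologs=2,
        n_pseudogenes=2, n_clusters=1, n_duplications=1,
        duplication_flank_nt=3000, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_predictions(small_cohort, matrix):
    params = Parameters(duplication_flank_nt=3000)
    return predict_species(
        small_cohort.contigs["sp01"], small_cohort.ref_db, params,
        matrix=matrix, ests=small_cohort.ests["sp01"], species="sp01",
    ), params


@pytest.fixture(scope="session")
def benchmark_cohort():
    """The 5-species, ~2 Mb benchmark cohort (defaults of the spec)."""
    return generate_cohort(SyntheticCohortSpec(seed=20240917))


@pytest.fixture(scope="session")
def benchmark_calls(benchmark_cohort, matrix, params):
    calls = []
    for sp in sorted(benchmark_cohort.contigs):
        calls.extend(predict_species(
            benchmark_cohort.contigs[sp], benchmark_cohort.ref_db, params,
            matrix=matrix, ests=benchmark_cohort.ests[sp], species=sp,
        ).calls)
    return calls
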