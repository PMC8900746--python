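import numpy as np
import pytest

from mcanary import synthetic_cohort as sc


@pytest.fixture
def toy_genome():
    return {"chr1": 120_000, "chr2": 120_000, "chr3": 120_000}


@pytest.fixture
def expression_refs():
    rng = np.random.default_rng(11)
    return sc.simulate_expression_reference(60, rng=rng)


@pytest.fixture
def tss_records(toy_genome, expression_refs):
    return sc.make_tss_records(toy_genome, sorted(expression_refs["BRCA"].genes()))


@pytest.fixture
def liver_fragments(toy_genome, tss_records, expression_refs):
    spec = sc.FragmentSimSpec(
        tissue="LIHC",
        genome=toy_genome,
        tss_records=tss_records,
        expression=expression_refs,
        seed=11,
    )
    frags, _ = sc.simulate_fragments(spec)
    return frags
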