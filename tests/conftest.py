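import numpy as np
import pytest

from pedaml import SimConfig, VariantCall, generate


def make_variant(**kw):
    """A clean missense call passing every exclusion; override per test."""
    base = dict(
        sample_id="S1", gene="KIT", chrom="chr4", pos=55_599_321,
        ref="A", alt="T", consequence="missense", protein_pos=816,
        aa_change="p.D816V", vaf=0.30, depth=100, mutant_reads=30,
        cosmic_count=0, kg_freq=None,
    )
    base.update(kw)
    return VariantCall(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort shared across statistical tests."""
    return generate(SimConfig(n_patients=400), seed=20260927 % 2**31)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
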