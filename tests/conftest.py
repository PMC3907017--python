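import pytest

from mztscope import (
    SyntheticConfig,
    generate_bundle,
    load_default_tables,
    run_pipeline,
)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic dataset (seed 42, 10 genes/class, dropout 0)."""
    return generate_bundle(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def annotation(bundle):
    """Annotation pipeline result on the default bundle."""
    return run_pipeline(
        bundle.reference,
        bundle.evidence,
        bundle.junctions,
        bundle.counts,
        bundle.peaks,
        bundle.rnapii,
    )


@pytest.fixture(scope="session")
def llr_table():
    return load_default_tables()
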