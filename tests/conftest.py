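import pytest

from ddpp_lung import SynthConfig, generate_cohort, generate_null_cohort, weight_matrix

# Desk-scale gene universe: keeps the full-transcriptome screen structure
# (planted signatures buried among thousands of null genes) at test runtime.
N_GENES = 2000


def make_config(**overrides) -> SynthConfig:
    overrides.setdefault("n_genes", N_GENES)
    return SynthConfig(**overrides)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Default-structure cohort with a deterministic DFS-weight link."""
    cfg = make_config(noise_sd=0.0, seed=7)
    expr, clinical, truth = generate_cohort(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-structure cohort at the default noise level."""
    cfg = make_config(seed=11)
    expr, clinical, truth = generate_cohort(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted structure at all."""
    cfg = make_config(seed=5)
    expr, clinical = generate_null_cohort(cfg)
    return cfg, expr, clinical


@pytest.fixture(scope="session")
def noiseless_weights(noiseless_cohort):
    _, expr, _, _ = noiseless_cohort
    return {src: weight_matrix(expr, src) for src in ("tumor", "normal")}


@pytest.fixture(scope="session")
def null_weights(null_cohort):
    _, expr, _ = null_cohort
    return {src: weight_matrix(expr, src) for src in ("tumor", "normal")}
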