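import pytest

from jejuquant.decontamination import DecontaminationConfig
from jejuquant.pipeline import PipelineConfig, even_abundance_design, run_pipeline, simulate_cohort
from jejuquant.synthetic_data import generate_reference_db


@pytest.fixture(scope="session")
def db():
    """Shared 50-species reference database."""
    return generate_reference_db(50, seed=1)


@pytest.fixture(scope="session")
def noiseless_run():
    """A 10-patient contaminant-free, error-free cohort pushed through the
    whole pipeline; the basis of the exact truth-recovery checks.

    The cross-sample singleton rule is disabled: a species genuinely present
    in one sample only would otherwise be removed by design.
    """
    design = even_abundance_design(n_patients=10, read_pairs=3000, seed=17)
    cohort = simulate_cohort(design, qpcr_noise_sd=0.0)
    config = PipelineConfig(
        decontamination=DecontaminationConfig(min_cross_sample_occurrence=1)
    )
    return cohort, run_pipeline(cohort, config)
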