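import pytest

from mutburden.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def ezh2_counts():
    """Per-line counts of variants in EZH2-binding sites (mRNA, retrovirus,
    Sendai replicate triplets) used as a worked example throughout."""
    return [[13.0, 11.0, 6.0], [1.0, 7.0, 2.0], [3.0, 0.0, 3.0]]


@pytest.fixture(scope="session")
def coding_counts():
    """Per-line coding-region mutation counts for the power worked example."""
    return [[27.0, 16.0, 9.0], [16.0, 20.0, 24.0], [12.0, 9.0, 5.0]]


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort under the default study conditions."""
    return generate_cohort(CohortConfig(seed=11))


def light_config(**overrides) -> CohortConfig:
    """A cohort configuration that only plants variants (no tracks-dependent
    annotation, caller emulation, integrations, SVs or traces) for
    replicate-heavy calibration studies."""
    base = dict(
        genome_spec=(("chr1", 200_000), ("chr2", 200_000)),
        annotate_truth=False,
        emulate_callers=False,
        include_integrations=False,
        include_svs=False,
        include_traces=False,
        n_known_variants=0,
    )
    base.update(overrides)
    return CohortConfig(**base)
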