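import pytest

from essprofile.synthetic_data import GroupEffectConfig, generate_cohort


@pytest.fixture(scope="session")
def small_effect_config() -> GroupEffectConfig:
    """Compact paper-direction cohort: same contrasts, smaller genes so the
    suite stays fast."""
    return GroupEffectConfig(
        n_essential=40,
        n_viable=60,
        gene_length_median=(6000.0, 4500.0),
        exon_total_median=(900.0, 700.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_effect_config):
    return generate_cohort(small_effect_config)
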