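import pandas as pd
import pytest

from adpatterns import canmat_rules, cohort_builder, synthetic_emr


@pytest.fixture(scope="session")
def catalog():
    return canmat_rules.load_catalog()


@pytest.fixture(scope="session")
def tiers():
    return canmat_rules.load_tier_table()


@pytest.fixture(scope="session")
def clean_population():
    config = synthetic_emr.SimConfig(n_patients=2000, seed=11)
    tables, truths = synthetic_emr.generate_population(config)
    return config, tables, truths


@pytest.fixture(scope="session")
def noisy_population():
    config = synthetic_emr.SimConfig(n_patients=1500, seed=23, mode="noisy")
    tables, truths = synthetic_emr.generate_population(config)
    return config, tables, truths


@pytest.fixture(scope="session")
def clean_pipeline(clean_population, catalog, tiers):
    """Full pipeline outputs on the clean population."""
    from adpatterns import concordance_classifier, pattern_engine

    config, tables, truths = clean_population
    cohort = cohort_builder.screen_patients(tables, catalog=catalog)
    levels, transitions = pattern_engine.run_pattern_engine(
        cohort, tables["prescriptions"], catalog
    )
    concordance = concordance_classifier.run_concordance(cohort, transitions, tiers)
    return {
        "config": config,
        "tables": tables,
        "truths": truths,
        "cohort": cohort,
        "levels": levels,
        "transitions": transitions,
        "concordance": concordance,
    }


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_population, catalog, tiers):
    from adpatterns import concordance_classifier, pattern_engine

    config, tables, truths = noisy_population
    cohort = cohort_builder.screen_patients(tables, catalog=catalog)
    levels, transitions = pattern_engine.run_pattern_engine(
        cohort, tables["prescriptions"], catalog
    )
    concordance = concordance_classifier.run_concordance(cohort, transitions, tiers)
    return {
        "config": config,
        "tables": tables,
        "truths": truths,
        "cohort": cohort,
        "levels": levels,
        "transitions": transitions,
        "concordance": concordance,
    }


def truth_by_pid(truths):
    return {t.patient_id: t for t in truths}
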