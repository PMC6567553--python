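"""Shared fixtures: synthetic study bundles built once per session."""

import pytest

import als_epi as ae


@pytest.fixture(scope="session")
def lsl_bundle():
    """Inner-London-like registry: 152 rows, fractional sector weights."""
    config = ae.GeneratorConfig.preset("lsl", seed=7)
    frame, truth = ae.gen_registry(config)
    return config, frame, truth, ae.cases_from_frame(frame)


@pytest.fixture(scope="session")
def canterbury_bundle():
    """Suburban/rural-like registry: 269 rows, whole-person weights."""
    config = ae.GeneratorConfig.preset("canterbury", seed=7)
    frame, truth = ae.gen_registry(config)
    return config, frame, truth, ae.cases_from_frame(frame)


@pytest.fixture(scope="session")
def seals_bundle():
    """Survival register: 953 rows with planted missing-onset/age records."""
    config = ae.GeneratorConfig.preset("seals", seed=7)
    frame, truth = ae.gen_registry(config)
    return config, frame, truth, ae.cases_from_frame(frame)


@pytest.fixture(scope="session")
def seals_samples(seals_bundle):
    _config, _frame, _truth, cases = seals_bundle
    kept, _audit = ae.apply_exclusions(cases, "survival")
    return ae.samples_from_cases(kept)


@pytest.fixture(scope="session")
def uk_fixture():
    """UK-scale projection bundle calibrated to the study's 2020 anchors."""
    config = ae.GeneratorConfig.preset("uk", seed=7)
    surface = ae.rate_surface(config)
    estimates = {
        (sex, band): ae.RateEstimate(
            rate=float(surface.at[band, sex]),
            ci_low=float(surface.at[band, sex]),
            ci_high=float(surface.at[band, sex]),
            ci_level=0.95,
            method="poisson_exact",
            n_events=1.0,
            person_years=1.0,
        )
        for sex in ae.SEXES
        for band in ae.BAND_LABELS
    }
    rate_table = ae.RateTable(estimates, study_years=14.0)
    proj_frame, _truth = ae.gen_projection(config)
    projection = ae.PopulationProjection(proj_frame)
    life = ae.LifeTable(ae.gen_life_table(config))
    durations = {"<40": 56.0, "40-79": 35.0, "80+": 26.0, "overall": 34.0}
    return config, rate_table, projection, life, durations
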