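import pytest

from mrkinetics import MRConfig, load_instrument_set, run_two_sample_mr


@pytest.fixture(scope="session")
def cigarettes_set():
    """Harmonized coffee-exposure / cigarettes-per-day instrument set."""
    return load_instrument_set("tag_cigarettes")


@pytest.fixture(scope="session")
def cotinine_set():
    return load_instrument_set("cotinine")


@pytest.fixture(scope="session")
def biobank_set():
    return load_instrument_set("ukb_cigarettes")


@pytest.fixture(scope="session")
def cigarettes_results(cigarettes_set):
    """All model x method results on the cigarettes/day outcome (seeded)."""
    config = MRConfig(seed=20170712)
    results = run_two_sample_mr(cigarettes_set, config)
    keyed = {}
    i = 0
    for model in config.models:
        for method in config.methods:
            keyed[(model, method)] = results[i]
            i += 1
    return keyed
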