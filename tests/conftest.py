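"""Shared fixtures: synthetic sites at the sizes the tests need.

Heavy artefacts (the stressed six-year site and its processed result) are
session-scoped so the cost is paid once.
"""

import numpy as np
import pytest

import fluepart as fp


def stressed_config(seed: int = 1, n_years: int = 6) -> fp.SyntheticConfig:
    n_days = int(365.25 * n_years) + 1
    return fp.SyntheticConfig(
        n_days=n_days, seed=seed,
        dry_spell_blocks=fp.synthetic.yearly_dry_season(n_years + 1))


@pytest.fixture(scope="session")
def stressed_site():
    """Six-year site with flue0=0.5, theta_crit=0.5 and default noise."""
    return fp.synthetic.generate_site(
        stressed_config(seed=1), fp.TruthParams(flue0=0.5, theta_crit=0.5))


@pytest.fixture(scope="session")
def stressed_result(stressed_site):
    """Processed single-source pipeline result for the stressed site."""
    return fp.process_site(
        stressed_site["series"], stressed_site["evi_samples"],
        sources=("splash150",),
        hyper=fp.FAST_HYPER.with_(outer_repeats=2),
        search_hyper=fp.SEARCH_HYPER.with_(outer_repeats=2),
        seed=11)


@pytest.fixture(scope="session")
def cleaned_series(stressed_site):
    return fp.qc.build_cleaned_series(stressed_site["series"],
                                      stressed_site["evi_samples"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
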