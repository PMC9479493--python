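import pytest

import dtipower as dp


@pytest.fixture
def make_scenario():
    """Scenario factory with the packaged cohort defaults filled in."""

    def _make(
        rate=2.0,
        sem=dp.SEM_LOW,
        t_days=90.0,
        m=1,
        n=20,
        seed=1,
        iterations=2000,
        **kwargs,
    ):
        return dp.Scenario(
            patient_group=dp.PATIENT_GROUP,
            control_group=dp.CONTROL_GROUP,
            decrease=dp.default_decrease(rate),
            error=dp.ErrorModel(sem),
            t_days=t_days,
            m=m,
            n_per_group=n,
            iterations=iterations,
            seed=seed,
            **kwargs,
        )

    return _make
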