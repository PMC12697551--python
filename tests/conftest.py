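import numpy as np
import pytest

from reformri import PhenotypeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_records(values, ages=None, sexes=None, batch="SITE", group="CN"):
    """Build minimal validated records from parallel value/covariate arrays."""
    values = np.asarray(values, float)
    n = len(values)
    ages = np.full(n, 50.0) if ages is None else np.asarray(ages, float)
    sexes = ["F"] * n if sexes is None else list(sexes)
    return [
        PhenotypeRecord(
            subject_id=f"s{i:05d}", age=float(ages[i]), sex=sexes[i],
            batch=batch, value=float(values[i]), group=group,
        )
        for i in range(n)
    ]
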