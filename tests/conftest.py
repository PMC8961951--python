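import math

import pytest

from arfdx import (
    AgeBandedULN,
    CalculatorConfig,
    UlnTables,
    default_thresholds,
)


@pytest.fixture(scope="session")
def flat_uln() -> UlnTables:
    """Single-band ULN tables injected explicitly by engine tests.

    PR interval 160 ms, ASO 200 IU/mL, anti-DNase B 300 IU/mL at every
    age, so tests never depend on the shipped default reference data.
    """
    def table(kind: str, limit: float) -> AgeBandedULN:
        return AgeBandedULN(
            measurement_kind=kind, bands=((0.0, math.inf, limit),)
        )

    return UlnTables(
        pr_interval=table("PR interval ms", 160.0),
        aso_titre=table("ASO titre IU/mL", 200.0),
        adb_titre=table("anti-DNase B titre IU/mL", 300.0),
    )


@pytest.fixture(scope="session")
def test_config(flat_uln) -> CalculatorConfig:
    """Engine configuration with explicit (test-injected) ULN tables."""
    return CalculatorConfig(thresholds=default_thresholds(), uln=flat_uln)
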