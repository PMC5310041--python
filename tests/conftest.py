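import pytest

from mitedef.synthetic_data import (
    DesignConfig,
    GeneratorConfig,
    ResistanceParams,
    ToleranceParams,
)


def small_config(seed: int = 0, **tolerance_overrides) -> GeneratorConfig:
    """A fast desk-scale configuration: 8 groups, ~2k surveyed hosts."""
    cfg = GeneratorConfig(
        design=DesignConfig(
            populations=4,
            years=2,
            n_per_group={"A": 52, "I": 18, "O": 5, "M": 175},
            n_mated_per_group={"A": 40, "I": 22},
        ),
        resistance=ResistanceParams(),
        tolerance=ToleranceParams(**tolerance_overrides),
        seed=seed,
    )
    cfg.validate()
    return cfg


@pytest.fixture
def tiny_config():
    return small_config(seed=5)
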