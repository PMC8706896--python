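import pandas as pd
import pytest

from lipidmrm.builder import build_method
from lipidmrm.rules import default_rules
from lipidmrm.simulate import (
    MaturationDesign,
    TREND_DOWN,
    TREND_UP,
    simulate_maturation,
)

NEUTRAL_CLASSES = ("PC", "DG", "TG", "FA", "SM", "PA")


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def full_method():
    """The complete default method (all 26 classes + 21 IS)."""
    return build_method()


def trend_panel(per_class: int = 12) -> list[tuple[str, str]]:
    """Synthetic compound panel covering all trend classes plus neutrals."""
    panel = []
    for cls in sorted(set(TREND_UP) | set(TREND_DOWN) | set(NEUTRAL_CLASSES)):
        panel.extend((f"{cls} synth{i:02d}", cls) for i in range(per_class))
    return panel


@pytest.fixture(scope="session")
def maturation_run():
    """One simulated maturation study under default conditions (seed 11)."""
    design = MaturationDesign()
    areas, samples, truth = simulate_maturation(design, trend_panel(), seed=11)
    return design, areas, samples, truth


def study_matrix(conc_long: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Wide concentration matrix restricted to study samples."""
    wide = conc_long.pivot(
        index="sample", columns="transition_id", values="conc_ug_g"
    )
    study = samples.loc[samples["role"] == "study", "sample"]
    return wide.loc[study]
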