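import numpy as np
import pandas as pd
import pytest

from flymet.allele import GenotypeMatrix
from flymet.synthetic import SyntheticConfig, gen_metabolite_panel


def make_panel(values: dict[str, list[float]], lines=None, stage="adult",
               sex="female", diet="SD") -> pd.DataFrame:
    """Tiny single-stratum panel from explicit metabolite values."""
    n = len(next(iter(values.values())))
    lines = lines or [f"L{i}" for i in range(1, n + 1)]
    base = {"line": lines, "stage": [stage] * n, "sex": [sex] * n,
            "diet": [diet] * n, "replicate": [1] * n}
    return pd.DataFrame({**base, **values})


@pytest.fixture(scope="session")
def basal_panel():
    """Default-condition basal panel (35 lines, 3 metabotypes) with truth."""
    return gen_metabolite_panel(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def virago_panel():
    """Panel with four planted virago lines, mirroring the studied design."""
    cfg = SyntheticConfig(seed=2, virago_lines=("L3", "L9", "L17", "L28"))
    return gen_metabolite_panel(cfg)


@pytest.fixture
def toy_genotypes():
    """4 lines x 10 sites, hand-constructed calls (0 ref / 1 alt)."""
    calls = np.array([
        [0, 1, 1, 1, 0, 0, 0, 0, 0, 0],   # A alt at sites 2,3,4 (1-based)
        [0, 0, 0, 1, 1, 0, 0, 0, 0, 0],   # B alt at sites 4,5
        [0, 1, 0, 0, 0, 1, 1, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0, 1, 1, 0],
    ], dtype=np.int8)
    sites = [f"2L:{100 * (j + 1)}" for j in range(10)]
    return GenotypeMatrix(calls=calls, lines=["A", "B", "C", "D"], sites=sites)
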