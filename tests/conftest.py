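import numpy as np
import pandas as pd
import pytest

from metaepi.pipeline import CHARACTERISTICS


def make_studies(ma_specs, characteristic="randomization", smd=0.5, var=0.1):
    """Build a toy arm-level table.

    ``ma_specs`` maps ma_id -> list of rating levels (one study per
    rating, one arm per study).
    """
    rows = []
    for ma_id, ratings in ma_specs.items():
        for i, rating in enumerate(ratings):
            row = {
                "ma_id": ma_id,
                "study_id": f"{ma_id}-S{i + 1}",
                "arm_id": f"{ma_id}-S{i + 1}-A1",
                "smd": smd + 0.1 * i,
                "var": var,
            }
            for c in CHARACTERISTICS:
                row[f"rob_{c}"] = "not_assessed"
            row[f"rob_{characteristic}"] = rating
            rows.append(row)
    return pd.DataFrame(rows)


def make_mas(ma_ids, direction="benefit_positive"):
    return pd.DataFrame(
        {
            "ma_id": list(ma_ids),
            "expected_direction": direction,
            "design": "therapeutic",
            "topic": "toy",
        }
    )


@pytest.fixture
def toy_dataset():
    """12 meta-analyses, each with 4 studies mixing rating levels, so
    'randomization' clears the 10-eligible-MA threshold."""
    specs = {
        f"MA{i:02d}": ["low", "high", "unclear", "low"] for i in range(1, 13)
    }
    rng = np.random.default_rng(42)
    studies = make_studies(specs)
    studies["smd"] = rng.normal(0.5, 0.4, len(studies))
    mas = make_mas(specs.keys())
    return studies, mas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
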