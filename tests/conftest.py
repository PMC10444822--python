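import hypothesis
import pandas as pd
import pytest

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def small_measurement_table() -> pd.DataFrame:
    """Hand-built long-format table: 3 species, complete molar triplets.

    sp1 monotone decreasing (inside the IC region), sp2 middle-largest
    (outside), sp3 equal areas (boundary, inside).  Unit widths so the
    areas equal the lengths.
    """
    rows = []
    areas = {
        "sp1": {"M1": 4.0, "M2": 2.0, "M3": 1.0},
        "sp2": {"M1": 1.0, "M2": 2.0, "M3": 1.0},
        "sp3": {"M1": 1.0, "M2": 1.0, "M3": 1.0},
    }
    for sp, teeth in areas.items():
        for tooth, area in teeth.items():
            rows.append((sp, f"{sp}_i1", "L", tooth, area, 1.0))
    return pd.DataFrame(rows, columns=["species_id", "individual_id", "side",
                                       "tooth", "length_mm", "width_mm"])
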