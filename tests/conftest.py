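import pandas as pd
import pytest

from bloomharvest import separation


@pytest.fixture
def wrp_dose_points():
    """Measured jar-test grid: the two printed points plus interior filler."""
    return [
        separation.DoseResponsePoint(1.25, 70.0),
        separation.DoseResponsePoint(2.5, 82.0),
        separation.DoseResponsePoint(5.0, 96.0),
        separation.DoseResponsePoint(9.0, 95.0),
    ]


@pytest.fixture
def water_table(tmp_path):
    """Two-column parameter/value physicochemistry table."""
    rows = [
        ("Temperature", 18.1), ("pH", 7.01), ("DO", 9.86),
        ("Conductivity", 302.1), ("Salinity", 0.17), ("Dry Weight", 0.13),
        ("Chlorophyll a", 443.23), ("F", 0.0), ("Cl", 26.49),
        ("NO2", 9.72), ("SO4", 6.0), ("Br", 0.0), ("NO3", 2.59),
        ("PO4", 6.11), ("Na", 16.85), ("NH4", 0.48), ("K", 4.02),
        ("Mg", 9.15), ("Ca", 37.42),
    ]
    path = tmp_path / "water.csv"
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)
    return path
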