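import numpy as np
import pandas as pd
import pytest

from resistx import DoseSeries, default_doses, hill_curve


@pytest.fixture
def doses9():
    """The default 9-point, 3-fold titration (top dose 10 uM)."""
    return default_doses()


@pytest.fixture
def clean_series(doses9):
    """Noise-free quadruplicate series from (top=1, bottom=0, ec50=1, slope=1)."""
    d = np.repeat(doses9, 4)
    return DoseSeries("cpd", "line", d, hill_curve(d, 1.0, 0.0, 1.0, 1.0))


@pytest.fixture
def simple_plate():
    """One plate: 3 vehicle wells and a 4-dose single-replicate titration."""
    rows = [
        ("P1", "A1", "L", "vehicle", 0.0, 1, 90_000.0, True),
        ("P1", "A2", "L", "vehicle", 0.0, 1, 100_000.0, True),
        ("P1", "A3", "L", "vehicle", 0.0, 1, 110_000.0, True),
        ("P1", "B1", "L", "drug", 0.1, 1, 100_000.0, False),
        ("P1", "B2", "L", "drug", 1.0, 1, 50_000.0, False),
        ("P1", "B3", "L", "drug", 10.0, 1, 10_000.0, False),
        ("P1", "B4", "L", "drug", 100.0, 1, 0.0, False),
    ]
    return pd.DataFrame(rows, columns=[
        "plate_id", "well", "cell_line", "compound", "dose_uM",
        "replicate", "signal", "is_vehicle"])
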