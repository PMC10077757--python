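"""Shared fixtures: small programmatically generated screen tables."""

import numpy as np
import pandas as pd
import pytest

from synscreen.dose_response import FourPLParams


@pytest.fixture
def six_dose_grid():
    return np.array([0.1, 1.0, 10.0, 100.0, 1_000.0, 10_000.0])


@pytest.fixture
def simple_screen_csv(tmp_path):
    """3-row monotherapy CSV with one DMSO (pos control) well."""
    path = tmp_path / "screen.csv"
    pd.DataFrame({
        "cell_line": ["L1", "L1", "L1"],
        "compound": ["drugA", "drugA", "DMSO"],
        "dose": [10.0, 100.0, 0.0],
        "unit": ["nM", "nM", "nM"],
        "replicate": [1, 1, 1],
        "signal": [8000.0, 4000.0, 10000.0],
        "role": ["sample", "sample", "pos_control"],
    }).to_csv(path, index=False)
    return path


@pytest.fixture
def plate_frame():
    """One-plate canonical frame with clean controls for normalization."""
    rows = [
        {"cell_line": "L1", "compound": "drugA", "dose": 10.0, "replicate": 1,
         "signal": 5000.0, "role": "sample"},
        {"cell_line": "L1", "compound": "drugA", "dose": 100.0, "replicate": 1,
         "signal": 10000.0, "role": "sample"},
        {"cell_line": "L1", "compound": "drugA", "dose": 1000.0, "replicate": 1,
         "signal": 10500.0, "role": "sample"},
        {"cell_line": "L1", "compound": "DMSO", "dose": 0.0, "replicate": 1,
         "signal": 9000.0, "role": "pos_control"},
        {"cell_line": "L1", "compound": "DMSO", "dose": 0.0, "replicate": 2,
         "signal": 11000.0, "role": "pos_control"},
        {"cell_line": "L1", "compound": "EMPTY", "dose": 0.0, "replicate": 1,
         "signal": 0.0, "role": "neg_control"},
        {"cell_line": "L1", "compound": "EMPTY", "dose": 0.0, "replicate": 2,
         "signal": 0.0, "role": "neg_control"},
    ]
    df = pd.DataFrame(rows)
    df["anchor_compound"] = None
    df["anchor_dose"] = 0.0
    return df


@pytest.fixture
def classic_params():
    """Full-kill reference curve: V(ec50) = 0.5."""
    return FourPLParams(e0=1.0, einf=0.0, ec50=10.0, hill=1.0)
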