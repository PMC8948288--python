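import numpy as np
import pandas as pd
import pytest


def make_wells(rows):
    """Build a well table from (seed, cell_line, set_id, rep, raw, is_ctrl, ctrl_name)."""
    return pd.DataFrame(
        [
            {
                "seed": r[0],
                "cell_line": r[1],
                "set_id": r[2],
                "plate_id": f"{r[2]}-P{r[3]}",
                "replicate": r[3],
                "raw_signal": r[4],
                "is_control": r[5],
                "control_name": r[6],
            }
            for r in rows
        ]
    )


@pytest.fixture
def simple_wells():
    """One cell line, one set: controls at 1000, one seed with two replicates."""
    return make_wells(
        [
            ("CTRL", "L1", "S1", 1, 1000.0, True, "siNT1"),
            ("CTRL", "L1", "S1", 2, 1000.0, True, "siNT1"),
            ("CTRL", "L1", "S1", 3, 1000.0, True, "siNT1"),
            ("AAAAAA", "L1", "S1", 1, 250.0, False, ""),
            ("AAAAAA", "L1", "S1", 2, 350.0, False, ""),
        ]
    )


@pytest.fixture
def toy_de():
    """Six DE rows built so exactly two pass the default filter chain.

    Filters: baseMean >= 1000, adjP < 0.05, log2FC < -1, match_count >= 1.
    G1/G4 pass; G2 fails baseMean, G3 fails adjP, G5 fails log2FC,
    G6 fails match_count.
    """
    return pd.DataFrame(
        {
            "gene": ["G1", "G2", "G3", "G4", "G5", "G6"],
            "baseMean": [2000.0, 500.0, 1500.0, 3000.0, 1200.0, 1100.0],
            "log2FC": [-2.0, -3.0, -2.5, -1.5, -0.5, -2.2],
            "adjP": [0.001, 0.001, 0.2, 0.01, 0.001, 0.001],
            "match_count": [3, 2, 1, 1, 2, 0],
        }
    )
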