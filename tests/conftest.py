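import numpy as np
import pandas as pd
import pytest

from pyrograss.phylo_models import load_tree


@pytest.fixture
def star_tree():
    labels = [f"s{i:03d}" for i in range(60)]
    newick = "(" + ",".join(f"{l}:1.0" for l in labels) + ");"
    return load_tree(newick), labels


@pytest.fixture
def occurrence_table():
    """Small occurrence table with known-good and known-bad records."""
    rows = [
        # species, lon, lat, date, hii, protected, lon_str, lat_str
        ("A", 23.1005, -11.250, "2005-06-01", 10, False),
        ("A", 23.1005, -11.250, "2005-06-01", 10, False),  # exact duplicate
        ("A", 24.5001, -12.333, "2003-01-15", 45, True),   # high HII, protected
        ("A", 25.1234, -13.001, "2001-03-02", 45, False),  # high HII, removed
        ("B", 181.0, 10.123, "2010-01-01", 5, False),      # lon out of range
        ("B", 0.0, 0.0, "2010-01-01", 5, False),           # null island
        ("B", 30.123, 5.456, "1979-12-31", 5, False),      # pre-1980
        ("B", 30.124, 5.457, "1980-01-01", 5, False),
        ("C", 31.1, 6.2, "2015-05-05", 5, False),          # low precision
    ]
    df = pd.DataFrame(
        rows, columns=["species", "lon", "lat", "date", "hii", "protected"]
    )
    df["lon_str"] = df["lon"].astype(str)
    df["lat_str"] = df["lat"].astype(str)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
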