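import numpy as np
import pandas as pd
import pytest

from dermattn.data_io import REQUIRED_COLUMNS

HAM_COUNTS = {"akiec": 327, "bcc": 514, "bkl": 1099, "df": 115,
              "mel": 1113, "nv": 6705, "vasc": 142}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_metadata_frame(counts: dict[str, int]) -> pd.DataFrame:
    """A minimal valid metadata table with the requested per-class counts."""
    rows = []
    i = 0
    for dx, n in counts.items():
        for _ in range(n):
            rows.append({
                "lesion_id": f"HAM_{i:07d}", "image_id": f"ISIC_{i:07d}",
                "dx": dx, "dx_type": "histo", "age": 50.0, "sex": "male",
                "localization": "back",
            })
            i += 1
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


@pytest.fixture
def ham_metadata_csv(tmp_path):
    """CSV fixture mirroring the HAM10000 class distribution."""
    path = tmp_path / "metadata.csv"
    make_metadata_frame(HAM_COUNTS).to_csv(path, index=False)
    return path
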