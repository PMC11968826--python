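from pathlib import Path

import numpy as np
import pytest

DATA_DIR = Path(__file__).parent / "data"

# Compact field size used throughout the suite; large enough that every
# detection window (nuclei >= 500 px, structures >= 400 px) is meaningful.
FIELD = (512, 512)


@pytest.fixture(scope="session")
def hist50() -> np.ndarray:
    """Bimodal 8-bit histogram with 50 occupied gray levels."""
    return np.loadtxt(DATA_DIR / "histogram_50bins.csv", dtype=int)
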