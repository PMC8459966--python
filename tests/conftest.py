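from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

REPO_ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = REPO_ROOT / "data"


@pytest.fixture(scope="session")
def hmgb1_fasta() -> Path:
    """Bundled canonical human HMGB1 sequence (UniProt P09429)."""
    return DATA_DIR / "hmgb1_human.fasta"


@pytest.fixture(scope="session")
def s1_table() -> Path:
    """User-supplied TSV export of the matrix-protein count table, if present."""
    return DATA_DIR / "s1_table.tsv"


@pytest.fixture(scope="session")
def s3_table() -> Path:
    """User-supplied TSV export of the truncated-matrix/urine table, if present."""
    return DATA_DIR / "s3_table.tsv"
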