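import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msa_outliers import Alignment, SequenceRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Five rows sharing one gap block; the last row's gaps are elsewhere."""
    rows = {
        "s1": "MKV--LIAG",
        "s2": "MKI--LIAG",
        "s3": "MRV--LIAG",
        "s4": "MKV--LLAG",
        "s5": "--VAGLI--",
    }
    return Alignment(records=tuple(
        SequenceRecord(id=k, residues=v) for k, v in rows.items()))


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(rows: dict[str, str], name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        return path
    return _write


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
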