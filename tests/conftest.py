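import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from drisee.seqio import SequenceRead


@pytest.fixture
def write_text(tmp_path):
    """Write literal text to a temp file and return its path."""

    def _write(content: str, name: str = "input.txt") -> Path:
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def make_bin_reads(prefix: str, suffixes: list[str], id_prefix: str = "r"):
    """Reads sharing `prefix` with the given non-prefix regions."""
    return [
        SequenceRead(id=f"{id_prefix}{i}", bases=prefix + s)
        for i, s in enumerate(suffixes)
    ]
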