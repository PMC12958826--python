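import random
from pathlib import Path

import pytest

from spsmap.alignments import AlignedRow, Alignment

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Location of optional externally-fetched inputs (UniProt FASTA files,
#: AlphaFold PDB models, ortholog alignments).  These cannot be bundled
#: with the repository; acceptance tests that need them fail with a clear
#: message when they are absent.
EXTERNAL_DATA = Path(__file__).resolve().parent.parent / "data" / "external"


def external_path(filename: str) -> Path:
    return EXTERNAL_DATA / filename


def random_alignment(n_rows, n_cols, rng, gap_rate=0.1, ref_id="r0"):
    rows = []
    for i in range(n_rows):
        chars = []
        for _ in range(n_cols):
            if i != 0 and rng.random() < gap_rate:
                chars.append("-")
            else:
                chars.append(rng.choice(AA))
        rows.append(AlignedRow(f"r{i}", "".join(chars)))
    return Alignment(rows, reference_id=ref_id)


@pytest.fixture
def rng():
    return random.Random(20240917)
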