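import numpy as np
import pandas as pd
import pytest

from riborhythm.annotation_io import (
    CoordinateMode,
    FootprintTable,
    TranscriptModel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_model():
    """60-nt transcript: 10 nt 5'UTR, 30 nt CDS, 20 nt 3'UTR."""
    seq = "GGCCATGTAA" + "ATG" + "GCT" * 8 + "TGA" + "C" * 20
    return TranscriptModel(
        transcript_id="toy", sequence=seq, utr5_len=10, cds_len=30, utr3_len=20
    )


def make_model(utr5: str, cds_codons: int = 10, utr3_len: int = 12,
               tid: str = "tx") -> TranscriptModel:
    """Model with a given 5'UTR sequence and an unremarkable CDS/3'UTR."""
    cds = "ATG" + "GCT" * (cds_codons - 2) + "TGA"
    seq = utr5 + cds + "C" * utr3_len
    return TranscriptModel(
        transcript_id=tid,
        sequence=seq,
        utr5_len=len(utr5),
        cds_len=len(cds),
        utr3_len=utr3_len,
    )


def psite_table(rows, sample_id="s1") -> FootprintTable:
    """P-site-mode table from (transcript_id, position, count) triples."""
    df = pd.DataFrame(
        [(t, p, 30, c) for t, p, c in rows],
        columns=["transcript_id", "position", "read_length", "count"],
    )
    return FootprintTable(
        sample_id=sample_id, data=df, coordinate_mode=CoordinateMode.PSITE
    )


@pytest.fixture
def ct_times():
    """CT0..CT24 at 4-h spacing, two replicates, pooled as 14 points."""
    return np.repeat(np.arange(0.0, 25.0, 4.0), 2)
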