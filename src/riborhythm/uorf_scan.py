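"""Upstream open reading frame (uORF) detection in 5'UTRs.

A uORF is a start codon in the 5'UTR together with the first downstream
stop codon in the same reading frame, both fully inside the 5'UTR.  The
minimal uORF is a bare start-stop pair (6 nt) encoding a zero-codon
peptide — the mouse Per2 5'UTR carries exactly such a uORF (ATGTAA),
whose mutation derepresses PER2 expression.

Start-codon classes:

* ``CANONICAL`` — ATG only.
* ``NEAR_COGNATE`` — the nine single-nucleotide variants of ATG
  (CTG, GTG, TTG, AAG, ACG, AGG, ATA, ATC, ATT), the standard definition
  of a near-cognate initiation codon.

Codons containing N never match a start or stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_io import TranscriptModel

STOP_CODONS = frozenset({"TGA", "TAA", "TAG"})
CANONICAL_STARTS = frozenset({"ATG"})
NEAR_COGNATE_STARTS = frozenset(
    {"CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT"}
)

CANONICAL = "canonical"
NEAR_COGNATE = "near_cognate"
CDS_OVERLAP = "cds_overlap"

_START_SETS = {
    CANONICAL: CANONICAL_STARTS,
    NEAR_COGNATE: NEAR_COGNATE_STARTS,
}

UORF_TABLE_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "length",
    "start_codon",
    "cognate_class",
    "distance_to_cds",
]


@dataclass(frozen=True)
class UORFRecord:
    """One detected uORF, in transcript coordinates (0-based, half-open)."""

    transcript_id: str
    start: int
    end: int
    start_codon: str
    cognate_class: str
    distance_d: int  # nt from uORF stop to the CDS start codon

    @property
    def length_L(self) -> int:
        return self.end - self.start

    @property
    def uorf_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"


def scan_uorfs(
    model: TranscriptModel,
    cognate_class: str = CANONICAL,
    all_stop_pairs: bool = False,
    allow_cds_overlap: bool = False,
) -> list[UORFRecord]:
    """Find all uORFs in a transcript's 5'UTR.

    Every start-codon occurrence yields at most one uORF terminating at
    the first in-frame stop codon inside the 5'UTR (``all_stop_pairs=True``
    instead emits one record per in-frame downstream stop).  Overlapping
    and nested uORFs from distinct starts are all reported, sorted by
    start position.

    With ``allow_cds_overlap=True``, a start codon with no in-frame stop
    inside the 5'UTR is extended into the CDS region to its first in-frame
    stop anywhere in the transcript and reported with the distinct class
    ``cds_overlap`` (negative distance to the CDS start).
    """
    if cognate_class not in _START_SETS:
        raise ValueError(f"unknown cognate_class {cognate_class!r}")
    starts = _START_SETS[cognate_class]
    utr = model.utr5_seq
    seq = model.sequence
    records: list[UORFRecord] = []
    for i in range(0, len(utr) - 2):
        codon = utr[i : i + 3]
        if codon not in starts:
            continue
        found_in_utr = False
        j = i + 3
        while j + 3 <= len(utr):
            if utr[j : j + 3] in STOP_CODONS:
                records.append(
                    UORFRecord(
                        transcript_id=model.transcript_id,
                        start=i,
                        end=j + 3,
                        start_codon=codon,
                        cognate_class=cognate_class,
                        distance_d=model.utr5_len - (j + 3),
                    )
                )
                found_in_utr = True
                if not all_stop_pairs:
                    break
            j += 3
        if not found_in_utr and allow_cds_overlap:
            j = i + 3
            while j + 3 <= len(seq):
                if seq[j : j + 3] in STOP_CODONS:
                    records.append(
                        UORFRecord(
                            transcript_id=model.transcript_id,
                            start=i,
                            end=j + 3,
                            start_codon=codon,
                            cognate_class=CDS_OVERLAP,
                            distance_d=model.utr5_len - (j + 3),
                        )
                    )
                    break
                j += 3
    records.sort(key=lambda r: (r.start, r.end))
    return records


def uorfs_to_table(uorf_lists: dict[str, list[UORFRecord]]) -> pd.DataFrame:
    """Flatten per-transcript uORF lists into the output table."""
    rows = [
        (
            r.transcript_id,
            r.start,
            r.end,
            r.length_L,
            r.start_codon,
            r.cognate_class,
            r.distance_d,
        )
        for records in uorf_lists.values()
        for r in records
    ]
    return pd.DataFrame(rows, columns=UORF_TABLE_COLUMNS)


def uorf_features(
    models: list[TranscriptModel],
    uorf_lists: dict[str, list[UORFRecord]],
) -> pd.DataFrame:
    """Per-transcript uORF features: count k, min distance, max length.

    Transcripts with no uORF carry k = 0 and missing (NaN) distance and
    length features.  ``uorf_lists`` must cover exactly the transcripts in
    ``models``.
    """
    model_ids = {m.transcript_id for m in models}
    if set(uorf_lists) != model_ids:
        raise ValueError("uorf_lists transcript set does not match models")
    rows = []
    for m in models:
        recs = uorf_lists[m.transcript_id]
        if recs:
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "n_uorfs": len(recs),
                    "min_distance": min(r.distance_d for r in recs),
                    "max_length": max(r.length_L for r in recs),
                    "total_uorf_nt": sum(r.length_L for r in recs),
                }
            )
        else:
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "n_uorfs": 0,
                    "min_distance": float("nan"),
                    "max_length": float("nan"),
                    "total_uorf_nt": 0,
                }
            )
    return pd.DataFrame(rows)
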