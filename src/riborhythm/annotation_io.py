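"""Transcript annotation, sequence, and footprint-table input/output.

Defines the shared coordinate convention for the whole package:
0-based, half-open, transcript-space positions, 5'->3'.  Each transcript
is partitioned into 5'UTR / CDS / 3'UTR, with the CDS including its stop
codon (so ``cds_len`` is always a multiple of 3).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

FOOTPRINT_COLUMNS = ["transcript_id", "position", "read_length", "count"]
STRUCTURE_COLUMNS = ["transcript_id", "utr5_len", "cds_len", "utr3_len"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "circadian_time", "replicate", "condition"]


class Region(str, enum.Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


class CoordinateMode(str, enum.Enum):
    FIVE_PRIME = "five_prime"
    PSITE = "psite"


class AnnotationError(ValueError):
    """Raised when annotation inputs violate the transcript-model contract."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's 5'UTR/CDS/3'UTR geometry plus its sequence.

    Parameters
    ----------
    transcript_id : str
        Unique identifier; each transcript id is treated independently
        (no gene-level isoform collapsing).
    sequence : str
        Uppercase ACGTN in transcript orientation (5'->3').
    utr5_len, cds_len, utr3_len : int
        Region lengths in nucleotides.  ``cds_len`` includes the stop
        codon and must be a positive multiple of 3.
    """

    transcript_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self):
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise AnnotationError(
                f"{self.transcript_id}: negative UTR length"
            )
        if self.cds_len <= 0:
            raise AnnotationError(f"{self.transcript_id}: cds_len must be positive")
        if self.cds_len % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: cds_len {self.cds_len} not a multiple of 3"
            )
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.sequence):
            raise AnnotationError(
                f"{self.transcript_id}: region lengths "
                f"({self.utr5_len}+{self.cds_len}+{self.utr3_len}) do not sum to "
                f"sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise AnnotationError(
                f"{self.transcript_id}: unexpected characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    @property
    def utr5_seq(self) -> str:
        return self.sequence[: self.utr5_len]

    @property
    def cds_seq(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


def region_of(model: TranscriptModel, position: int) -> Region:
    """Map a transcript position to its region (total over [0, length))."""
    if not 0 <= position < model.length:
        raise AnnotationError(
            f"{model.transcript_id}: position {position} outside [0, {model.length})"
        )
    if position < model.utr5_len:
        return Region.UTR5
    if position < model.cds_end:
        return Region.CDS
    return Region.UTR3


@dataclass
class FootprintTable:
    """Per-sample footprint counts at transcript positions.

    ``data`` holds one row per (transcript_id, position, read_length) with a
    strictly positive ``count``.  ``coordinate_mode`` says whether positions
    are raw read 5' ends or already P-site shifted.
    """

    sample_id: str
    data: pd.DataFrame
    coordinate_mode: CoordinateMode = CoordinateMode.FIVE_PRIME

    def __post_init__(self):
        df = self.data
        missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
        if missing:
            raise AnnotationError(f"footprint table missing columns {missing}")
        self.data = df[FOOTPRINT_COLUMNS].reset_index(drop=True)

    @property
    def total_count(self) -> int:
        return int(self.data["count"].sum())

    def counts_for(self, transcript_id: str) -> pd.DataFrame:
        """Counts pooled over read length for one transcript, by position."""
        sub = self.data[self.data["transcript_id"] == transcript_id]
        return sub.groupby("position", as_index=False)["count"].sum()


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    circadian_time: float
    replicate: int
    condition: str = "WT"

    def __post_init__(self):
        if self.circadian_time < 0:
            raise AnnotationError(f"{self.sample_id}: negative circadian_time")
        if self.replicate < 1:
            raise AnnotationError(f"{self.sample_id}: replicate must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers


def _structure_from_bed12(path) -> pd.DataFrame:
    """Derive (utr5_len, cds_len, utr3_len) from a BED12 file.

    The BED12 is interpreted in genome space per record; block projection
    turns thickStart/thickEnd into transcript-space CDS bounds.  Only plus
    and minus strands on single records are supported.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"BED12 line has {len(f)} fields: {line!r}")
            chrom_start = int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            tx_len = sum(sizes)

            def to_tx(gpos: int) -> int:
                # project a genomic coordinate onto transcript coordinates
                acc = 0
                for bs, bsz in zip(starts, sizes):
                    g0 = chrom_start + bs
                    if gpos <= g0:
                        return acc
                    if gpos <= g0 + bsz:
                        return acc + (gpos - g0)
                    acc += bsz
                return acc

            lo, hi = to_tx(thick_start), to_tx(thick_end)
            if strand == "-":
                lo, hi = tx_len - hi, tx_len - lo
            rows.append(
                {
                    "transcript_id": name,
                    "utr5_len": lo,
                    "cds_len": hi - lo,
                    "utr3_len": tx_len - hi,
                }
            )
    return pd.DataFrame(rows, columns=STRUCTURE_COLUMNS)


def read_structure_table(path) -> pd.DataFrame:
    """Read a 4-column structure TSV, or a BED12 file (by .bed suffix)."""
    if str(path).endswith(".bed"):
        return _structure_from_bed12(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STRUCTURE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"structure table missing columns {missing}")
    return df[STRUCTURE_COLUMNS]


def write_structure_table(models: list[TranscriptModel], path) -> None:
    df = pd.DataFrame(
        [
            (m.transcript_id, m.utr5_len, m.cds_len, m.utr3_len)
            for m in models
        ],
        columns=STRUCTURE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_fasta(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.transcript_id}\n")
            for i in range(0, len(m.sequence), 60):
                fh.write(m.sequence[i : i + 60] + "\n")


def read_transcript_models(
    fasta_path, structure_path, return_rejections: bool = False
):
    """Build validated TranscriptModels from a FASTA and structure table.

    Transcripts violating the model invariants (e.g. CDS length not a
    multiple of 3, lengths not summing to the sequence length) are dropped
    and reported via logging; a structured transcript with no sequence in
    the FASTA is a hard error.
    """
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    structure = read_structure_table(structure_path)
    models: list[TranscriptModel] = []
    rejections: list[tuple[str, str]] = []
    for row in structure.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            raise AnnotationError(f"no FASTA sequence for structured transcript {tid}")
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    sequence=seqs[tid],
                    utr5_len=int(row.utr5_len),
                    cds_len=int(row.cds_len),
                    utr3_len=int(row.utr3_len),
                )
            )
        except AnnotationError as exc:
            rejections.append((tid, str(exc)))
            logger.warning("rejected transcript %s: %s", tid, exc)
    if return_rejections:
        return models, rejections
    return models


def read_footprints(
    tsv_path,
    coordinate_mode: CoordinateMode = CoordinateMode.FIVE_PRIME,
    models: list[TranscriptModel] | None = None,
    sample_id: str | None = None,
) -> FootprintTable:
    """Read a 4-column footprint TSV into a validated FootprintTable.

    Duplicate (transcript, position, read_length) keys are summed with a
    warning.  Negative counts or positions are hard errors.  If ``models``
    is given, transcripts are checked against it and positions against the
    transcript length.
    """
    df = pd.read_csv(
        tsv_path,
        sep="\t",
        dtype={
            "transcript_id": str,
            "position": np.int64,
            "read_length": np.int64,
            "count": np.int64,
        },
    )
    if df.empty and not set(FOOTPRINT_COLUMNS) <= set(df.columns):
        df = pd.DataFrame(columns=FOOTPRINT_COLUMNS)
    missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"footprint table missing columns {missing}")
    if len(df):
        if (df["count"] <= 0).any():
            raise AnnotationError("footprint counts must be strictly positive")
        if (df["position"] < 0).any():
            raise AnnotationError("footprint positions must be non-negative")
        dup = df.duplicated(subset=["transcript_id", "position", "read_length"])
        if dup.any():
            logger.warning(
                "%s: %d duplicate footprint keys summed", tsv_path, int(dup.sum())
            )
            df = df.groupby(
                ["transcript_id", "position", "read_length"], as_index=False
            )["count"].sum()
        if models is not None:
            lengths = {m.transcript_id: m.length for m in models}
            unknown = set(df["transcript_id"]) - set(lengths)
            if unknown:
                raise AnnotationError(
                    f"footprints reference unknown transcripts: {sorted(unknown)[:5]}"
                )
            lim = df["transcript_id"].map(lengths)
            if (df["position"] >= lim).any():
                bad = df.loc[df["position"] >= lim, "transcript_id"].iloc[0]
                raise AnnotationError(f"position beyond transcript length for {bad}")
    if sample_id is None:
        sample_id = str(tsv_path)
    return FootprintTable(sample_id=sample_id, data=df, coordinate_mode=coordinate_mode)


def write_footprints(table: FootprintTable, path) -> None:
    df = table.data.sort_values(FOOTPRINT_COLUMNS[:3], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"sample sheet missing columns {missing}")
    metas = [
        SampleMeta(
            sample_id=str(r.sample_id),
            circadian_time=float(r.circadian_time),
            replicate=int(r.replicate),
            condition=str(r.condition),
        )
        for r in df.itertuples(index=False)
    ]
    keys = [(m.circadian_time, m.replicate, m.condition) for m in metas]
    if len(set(keys)) != len(keys):
        raise AnnotationError("(circadian_time, replicate, condition) not unique")
    return metas


def write_sample_sheet(metas: list[SampleMeta], path) -> None:
    pd.DataFrame(
        [
            (m.sample_id, m.circadian_time, m.replicate, m.condition)
            for m in metas
        ],
        columns=SAMPLE_SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
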