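"""Dataset loading and stage wiring shared by the CLI and scripts.

A dataset directory is the on-disk contract between stages: FASTA +
structure table, per-sample footprint TSVs named by sample id, a sample
sheet, and optionally a protein time-course TSV (see ``synthetic_data``
for a generator that emits exactly this layout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import footprint_quant as fq
from . import integrative, rhythm_stats, uorf_scan
from .annotation_io import (
    CoordinateMode,
    FootprintTable,
    SampleMeta,
    TranscriptModel,
    read_footprints,
    read_sample_sheet,
    read_transcript_models,
)

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    models: list[TranscriptModel]
    metas: list[SampleMeta]
    tables: list[FootprintTable]  # same order as metas, FIVE_PRIME mode
    protein: pd.DataFrame | None = None

    @classmethod
    def load(cls, path) -> "Dataset":
        path = Path(path)
        models = read_transcript_models(path / "transcripts.fa", path / "structure.tsv")
        metas = read_sample_sheet(path / "sample_sheet.tsv")
        tables = [
            read_footprints(
                path / "footprints" / f"{m.sample_id}.tsv",
                CoordinateMode.FIVE_PRIME,
                models=models,
                sample_id=m.sample_id,
            )
            for m in metas
        ]
        protein_path = path / "protein.tsv"
        protein = (
            pd.read_csv(protein_path, sep="\t") if protein_path.exists() else None
        )
        return cls(models=models, metas=metas, tables=tables, protein=protein)

    @property
    def times(self) -> np.ndarray:
        return np.array([m.circadian_time for m in self.metas])

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.metas]


def psite_tables(ds: Dataset, cfg: fq.QuantConfig) -> list[FootprintTable]:
    return [fq.assign_psites(t, cfg, ds.models) for t in ds.tables]


def qc_tables(ds: Dataset, cfg: fq.QuantConfig):
    """Per-sample region read fractions and frame periodicity."""
    psites = psite_tables(ds, cfg)
    region_rows, frame_rows = [], []
    for t in psites:
        rq = fq.region_quant(t, ds.models)
        tot = rq[["reads_utr5", "reads_cds", "reads_utr3"]].sum()
        total = tot.sum()
        region_rows.append(
            {
                "sample_id": t.sample_id,
                "frac_utr5": tot["reads_utr5"] / total if total else np.nan,
                "frac_cds": tot["reads_cds"] / total if total else np.nan,
                "frac_utr3": tot["reads_utr3"] / total if total else np.nan,
            }
        )
        f0, f1, f2 = fq.frame_distribution(t, ds.models)
        frame_rows.append(
            {"sample_id": t.sample_id, "frame0": f0, "frame1": f1, "frame2": f2}
        )
    return pd.DataFrame(region_rows), pd.DataFrame(frame_rows)


def well_translated_verdicts(
    ds: Dataset, cfg: fq.QuantConfig, pool_samples: bool = True
) -> pd.DataFrame:
    return fq.well_translated_table(
        psite_tables(ds, cfg), ds.models, cfg, pool_samples=pool_samples
    )


def uorf_results(ds: Dataset, cfg: fq.QuantConfig, cognate_class: str):
    """uORF catalogue plus per-sample uORF counts/RPKM."""
    lists = {
        m.transcript_id: uorf_scan.scan_uorfs(m, cognate_class) for m in ds.models
    }
    catalogue = uorf_scan.uorfs_to_table(lists)
    all_records = [r for recs in lists.values() for r in recs]
    counts = pd.concat(
        [fq.allocate_uorf_reads(t, all_records) for t in psite_tables(ds, cfg)],
        ignore_index=True,
    )
    return catalogue, counts, lists


def cds_rpkm_matrix(
    ds: Dataset, cfg: fq.QuantConfig, transcripts: list[str] | None = None
) -> pd.DataFrame:
    """Transcript-by-sample CDS RPKM matrix (columns in sample order)."""
    frames = []
    for t in psite_tables(ds, cfg):
        rq = fq.region_quant(t, ds.models)
        frames.append(rq.set_index("transcript_id")["rpkm_cds"].rename(t.sample_id))
    mat = pd.concat(frames, axis=1)
    if transcripts is not None:
        mat = mat.loc[transcripts]
    return mat


def uorf_rpkm_matrix(counts: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    mat = counts.pivot_table(
        index="uorf_id", columns="sample_id", values="rpkm", aggfunc="first"
    )
    return mat.reindex(columns=sample_ids)


def protein_matrix(ds: Dataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature-by-sample protein matrix with its time vector."""
    if ds.protein is None:
        raise FileNotFoundError("dataset has no protein.tsv")
    prot = ds.protein.copy()
    prot["sample"] = (
        "CT"
        + prot["circadian_time"].astype(int).astype(str).str.zfill(2)
        + "_R"
        + prot["replicate"].astype(str)
    )
    mat = prot.pivot_table(
        index="feature_id", columns="sample", values="copies_per_cell", aggfunc="first"
    )
    key = prot.drop_duplicates("sample").set_index("sample")["circadian_time"]
    order = key.sort_values(kind="mergesort").index
    mat = mat.reindex(columns=order)
    return mat, key.loc[order].to_numpy(dtype=float)


def rhythm_results(
    matrix: pd.DataFrame,
    times: np.ndarray,
    periods=(24.0,),
    phase_step: float = 4.0,
) -> pd.DataFrame:
    """JTK + cosinor + BH over a feature-by-sample matrix."""
    matrix = matrix.dropna(axis=0, how="any")
    return rhythm_stats.rhythm_table(matrix, times, periods, phase_step)


def integrate(
    ds: Dataset,
    cfg: fq.QuantConfig,
    periods=(24.0,),
    phase_step: float = 4.0,
    alpha: float = 0.05,
    rna_rpkm: pd.DataFrame | None = None,
    k_max: int = 5,
):
    """Phase-delay, efficiency, and uORF-dose tables in one pass.

    Translation efficiency requires an RNA RPKM matrix; when absent the
    TE columns are skipped with a logged notice.
    """
    rpkm = cds_rpkm_matrix(ds, cfg)
    ribo_rhythms = rhythm_results(rpkm, ds.times, periods, phase_step)
    pmat, ptimes = protein_matrix(ds)
    prot_rhythms = rhythm_results(pmat, ptimes, periods, phase_step)
    delays = integrative.phase_delay(ribo_rhythms, prot_rhythms)
    delays = delays.merge(
        ribo_rhythms[["feature_id", "p_adj"]].rename(columns={"p_adj": "p_adj_ribo"}),
        on="feature_id",
        how="left",
    ).merge(
        prot_rhythms[["feature_id", "p_adj"]].rename(
            columns={"p_adj": "p_adj_protein"}
        ),
        on="feature_id",
        how="left",
    )

    times = ds.times
    ribo_long = (
        rpkm.reset_index()
        .melt(id_vars="transcript_id", var_name="sample_id", value_name="value")
        .rename(columns={"transcript_id": "feature_id"})
    )
    ribo_long["t"] = ribo_long["sample_id"].map(
        dict(zip(ds.sample_ids, times))
    )
    prot_long = (
        pmat.reset_index()
        .melt(id_vars="feature_id", var_name="sample", value_name="value")
    )
    pkey = dict(zip(pmat.columns, ptimes))
    prot_long["t"] = prot_long["sample"].map(pkey)
    rna_long = None
    if rna_rpkm is not None:
        rna_long = (
            rna_rpkm.reset_index()
            .melt(id_vars=rna_rpkm.index.name or "index",
                  var_name="sample_id", value_name="value")
        )
        rna_long.columns = ["feature_id", "sample_id", "value"]
        rna_long["t"] = rna_long["sample_id"].map(dict(zip(ds.sample_ids, times)))
    else:
        logger.info("no RNA table supplied; translation-efficiency columns skipped")
    per_t, means = integrative.efficiency_ratios(
        prot_long[["feature_id", "t", "value"]],
        ribo_long[["feature_id", "t", "value"]],
        rna_long[["feature_id", "t", "value"]] if rna_long is not None else None,
    )

    lists = {
        m.transcript_id: uorf_scan.scan_uorfs(m, uorf_scan.CANONICAL)
        for m in ds.models
    }
    features = uorf_scan.uorf_features(ds.models, lists)
    mean_rpkm = rpkm.mean(axis=1)
    dose_summary, trend = integrative.uorf_dose_stratification(
        features, mean_rpkm, k_max=k_max
    )
    return {
        "ribo_rhythms": ribo_rhythms,
        "protein_rhythms": prot_rhythms,
        "phase_delay": delays,
        "efficiency_per_timepoint": per_t,
        "efficiency_means": means,
        "dose_summary": dose_summary,
        "dose_trend": trend,
    }
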