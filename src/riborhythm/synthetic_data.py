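"""Synthetic circadian ribosome-profiling experiments with known truth.

Generates everything the pipeline consumes — transcript sequences with
planted uORFs, per-sample footprint tables, a sample sheet, and a
protein time course — from a single seeded configuration, so every
analysis stage can be checked against planted ground truth without any
external data.

The default design mirrors a liver ribosome-profiling time course:
7 circadian timepoints (CT0..CT24, 4-h spacing) x 2 replicates,
cosine-modulated negative-binomial footprint counts, 5'UTR uORFs whose
count represses CDS occupancy multiplicatively (factor ``r`` per uORF),
3-nt reading-frame periodicity, and region-biased read placement.
uORF-region reads carry their own rhythm, phase-advanced by a small lead
relative to the CDS rhythm.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    CoordinateMode,
    FootprintTable,
    SampleMeta,
    TranscriptModel,
    write_fasta,
    write_footprints,
    write_sample_sheet,
    write_structure_table,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = ("TGA", "TAA", "TAG")
_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
# CDS interior: anything but a stop.  uORF interior: additionally no ATG,
# so a planted uORF contains no nested canonical start.
_NONSTOP_CODONS = np.array([c for c in _ALL_CODONS if c not in _STOPS])
_SAFE_UORF_CODONS = np.array(
    [c for c in _ALL_CODONS if c not in _STOPS and c != "ATG"]
)
_READ_LENGTHS = np.arange(26, 33)
_READ_LENGTH_PROBS = np.array([0.03, 0.08, 0.18, 0.35, 0.22, 0.10, 0.04])
_PSITE_OFFSET = 12


@dataclass
class SimConfig:
    """Parameters of a synthetic experiment.

    Rates are per sample unless noted.  ``library_size`` is the expected
    number of footprint reads per sample; per-transcript expression is
    log-normal and normalized so expected totals match it.
    ``uorf_count_choices``, when set, draws uORF counts uniformly from
    the given values instead of Poisson(``uorf_plant_rate``) — used for
    dose-response designs with balanced strata.
    """

    n_transcripts: int = 2000
    utr5_len_range: tuple[int, int] = (60, 240)
    cds_codon_range: tuple[int, int] = (80, 400)
    utr3_len_range: tuple[int, int] = (50, 300)
    uorf_plant_rate: float = 0.8
    uorf_count_choices: tuple[int, ...] | None = None
    repression_factor_r: float = 0.6
    frac_rhythmic: float = 0.2
    amplitude_rel_range: tuple[float, float] = (0.3, 0.6)
    phase_mode_hours: float = 0.0
    phase_kappa: float = 2.0  # 0 => uniform phases
    nb_dispersion: float = 0.1
    frame_bias: tuple[float, float, float] = (0.6, 0.25, 0.15)
    region_weights: tuple[float, float, float] = (0.1, 1.0, 0.02)
    uorf_occupancy_range: tuple[float, float] = (0.5, 2.0)
    uorf_phase_lead_hours: float = 2.0
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    replicates: int = 2
    library_size: int = 200_000
    expr_sigma: float = 1.0
    scrub_background: bool = True
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.frame_bias), 1.0):
            raise ValueError("frame_bias must sum to 1")
        for name in ("uorf_plant_rate", "frac_rhythmic", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.repression_factor_r <= 1:
            raise ValueError("repression_factor_r must be in (0, 1]")
        if self.frac_rhythmic > 1:
            raise ValueError("frac_rhythmic must be <= 1")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted parameters, exactly consistent with the emitted files."""

    transcripts: pd.DataFrame  # transcript_id, rhythmic, amplitude, phase, ...
    uorfs: pd.DataFrame  # transcript_id, start, end, rel_occupancy


# ---------------------------------------------------------------------------
# sequence construction


def _random_bases(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrub_offtarget_atg(seq: list[str], planted, rng, max_iter: int = 500):
    """Mutate bases so no ATG trigram survives outside planted starts.

    ``planted`` is a list of (start, end) uORF intervals; their start and
    stop codons are immutable, and in-frame interior codons must stay
    non-stop and non-ATG after any mutation.
    """
    protected = set()
    interiors = []  # (lo, hi) of interior codon region, plus frame anchor
    starts = {s for s, _ in planted}
    for s, e in planted:
        protected.update(range(s, s + 3))
        protected.update(range(e - 3, e))
        interiors.append((s + 3, e - 3, s))

    def interior_ok(p: int, base: str) -> bool:
        for lo, hi, anchor in interiors:
            if lo <= p < hi:
                c0 = anchor + 3 * ((p - anchor) // 3)
                codon = "".join(seq[c0 : c0 + 3])
                codon = codon[: p - c0] + base + codon[p - c0 + 1 :]
                return codon not in _STOPS and codon != "ATG"
        return True

    for _ in range(max_iter):
        text = "".join(seq)
        hit = -1
        i = text.find("ATG")
        while i != -1:
            if i not in starts:
                hit = i
                break
            i = text.find("ATG", i + 1)
        if hit == -1:
            return
        positions = [p for p in (hit, hit + 1, hit + 2) if p not in protected]
        rng.shuffle(positions)
        done = False
        for p in positions:
            options = [b for b in "ACGT" if b != seq[p] and interior_ok(p, b)]
            if options:
                seq[p] = options[rng.integers(0, len(options))]
                done = True
                break
        if not done:  # pragma: no cover - geometrically impossible by design
            raise RuntimeError("could not scrub ATG at a fully protected site")
    raise RuntimeError("ATG scrubbing did not converge")


def _build_utr5(rng, length: int, n_uorfs: int, scrub: bool):
    """Random 5'UTR with ``n_uorfs`` planted non-overlapping uORFs."""
    for _ in range(50):
        lengths = 6 + 3 * rng.integers(0, 9, size=n_uorfs)
        if lengths.sum() <= length:
            break
        if n_uorfs > 0 and 6 * n_uorfs > length:
            n_uorfs -= 1  # shrink toward feasibility before giving up
    else:
        raise RuntimeError("cannot fit planted uORFs into the 5'UTR")
    free = length - int(lengths.sum())
    gaps = rng.multinomial(free, np.full(n_uorfs + 1, 1.0 / (n_uorfs + 1)))
    seq: list[str] = []
    planted: list[tuple[int, int]] = []
    pos = 0
    for k in range(n_uorfs):
        seq.append(_random_bases(rng, gaps[k]))
        pos += int(gaps[k])
        start = pos
        interior_codons = (int(lengths[k]) - 6) // 3
        body = (
            "ATG"
            + "".join(_SAFE_UORF_CODONS[rng.integers(0, len(_SAFE_UORF_CODONS),
                                                     size=interior_codons)])
            + _STOPS[rng.integers(0, 3)]
        )
        seq.append(body)
        pos += len(body)
        planted.append((start, pos))
    seq.append(_random_bases(rng, int(gaps[n_uorfs])))
    chars = list("".join(seq))
    assert len(chars) == length
    if scrub:
        _scrub_offtarget_atg(chars, planted, rng)
    return "".join(chars), planted


def _build_cds(rng, n_codons: int) -> str:
    body = "".join(
        _NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)]
    )
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def simulate_transcriptome(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate transcript models with planted uORFs plus ground truth.

    With ``scrub_background`` (default) the 5'UTR carries no canonical
    start codon other than the planted ones, so a canonical uORF scan
    recovers exactly the planted intervals; without scrubbing the scan
    returns a superset (planted plus chance uORFs).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    models: list[TranscriptModel] = []
    tx_rows, uorf_rows = [], []
    base_expr = rng.lognormal(mean=0.0, sigma=cfg.expr_sigma, size=cfg.n_transcripts)
    rhythmic = rng.random(cfg.n_transcripts) < cfg.frac_rhythmic
    amplitude = np.where(
        rhythmic, rng.uniform(*cfg.amplitude_rel_range, size=cfg.n_transcripts), 0.0
    )
    if cfg.phase_kappa > 0:
        phases = (
            rng.vonmises(
                2 * np.pi * cfg.phase_mode_hours / 24.0,
                cfg.phase_kappa,
                size=cfg.n_transcripts,
            )
            * 24.0
            / (2 * np.pi)
        ) % 24.0
    else:
        phases = rng.uniform(0.0, 24.0, size=cfg.n_transcripts)
    if cfg.uorf_count_choices is not None:
        k_counts = rng.choice(
            np.asarray(cfg.uorf_count_choices), size=cfg.n_transcripts
        )
    else:
        k_counts = rng.poisson(cfg.uorf_plant_rate, size=cfg.n_transcripts)
    for i in range(cfg.n_transcripts):
        tid = f"TX{i:05d}"
        u5_len = int(rng.integers(*cfg.utr5_len_range))
        n_codons = int(rng.integers(*cfg.cds_codon_range))
        u3_len = int(rng.integers(*cfg.utr3_len_range))
        utr5, planted = _build_utr5(rng, u5_len, int(k_counts[i]), cfg.scrub_background)
        seq = utr5 + _build_cds(rng, n_codons) + _random_bases(rng, u3_len)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                sequence=seq,
                utr5_len=u5_len,
                cds_len=3 * n_codons,
                utr3_len=u3_len,
            )
        )
        tx_rows.append(
            {
                "transcript_id": tid,
                "rhythmic": bool(rhythmic[i]),
                "amplitude": float(amplitude[i]),
                "phase": float(phases[i]),
                "base_expr": float(base_expr[i]),
                "n_uorfs": len(planted),
            }
        )
        for s, e in planted:
            uorf_rows.append(
                {
                    "transcript_id": tid,
                    "start": s,
                    "end": e,
                    "rel_occupancy": float(rng.uniform(*cfg.uorf_occupancy_range)),
                }
            )
    truth = GroundTruth(
        transcripts=pd.DataFrame(tx_rows),
        uorfs=pd.DataFrame(
            uorf_rows, columns=["transcript_id", "start", "end", "rel_occupancy"]
        ),
    )
    return models, truth


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.clip(mean, 0.0, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


def _modulation(t: float, amplitude: np.ndarray, phase: np.ndarray) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2 * np.pi * (t - phase) / 24.0)


def simulate_footprints(
    models: list[TranscriptModel],
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Draw per-sample footprint tables (FIVE_PRIME mode) and a sample sheet.

    Expected CDS depth at time t is mesor * (1 + A cos(2 pi (t - phi)/24))
    multiplied by r^k for k planted uORFs; reads land on codons with the
    configured frame bias; 5'UTR/3'UTR background and uORF-interval reads
    follow the region weights, uORF reads with a phase lead.  Counts are
    negative-binomial at the transcript-region level; emitted positions
    are read 5' ends (P-site minus the standard +12 offset; reads whose
    5' end would fall before the transcript start are dropped).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    tx = truth.transcripts
    n_tx = len(models)
    u5 = np.array([m.utr5_len for m in models])
    cds_len = np.array([m.cds_len for m in models])
    u3 = np.array([m.utr3_len for m in models])
    n_codons = cds_len // 3
    tids = np.array([m.transcript_id for m in models])

    k = tx["n_uorfs"].to_numpy()
    base = tx["base_expr"].to_numpy()
    amp = tx["amplitude"].to_numpy()
    phase = tx["phase"].to_numpy()
    w5, wc, w3 = cfg.region_weights
    repress = cfg.repression_factor_r ** k

    # per-nt mean rates before library normalization (cycle-averaged)
    lam_cds = base * repress * wc
    lam_u5 = base * w5
    lam_u3 = base * w3
    uo = truth.uorfs
    uo_tx_idx = (
        uo["transcript_id"].map({t: i for i, t in enumerate(tids)}).to_numpy(dtype=int)
        if len(uo)
        else np.zeros(0, dtype=int)
    )
    uo_len = (uo["end"] - uo["start"]).to_numpy() if len(uo) else np.zeros(0)
    lam_uorf = (
        base[uo_tx_idx] * wc * uo["rel_occupancy"].to_numpy()
        if len(uo)
        else np.zeros(0)
    )
    expected_total = (
        (lam_cds * cds_len).sum()
        + (lam_u5 * u5).sum()
        + (lam_u3 * u3).sum()
        + (lam_uorf * uo_len).sum()
    )
    scale = cfg.library_size / expected_total

    frame_bias = np.asarray(cfg.frame_bias)
    tables: list[FootprintTable] = []
    metas: list[SampleMeta] = []
    for t in cfg.timepoints:
        mod_cds = _modulation(t, amp, phase)
        mod_uorf = _modulation(
            t,
            amp[uo_tx_idx] if len(uo) else np.zeros(0),
            (phase[uo_tx_idx] - cfg.uorf_phase_lead_hours) % 24.0
            if len(uo)
            else np.zeros(0),
        )
        for rep in range(1, cfg.replicates + 1):
            sample_id = f"CT{int(t):02d}_R{rep}"
            parts = []

            # CDS reads: codon-uniform, frame-biased within the codon
            totals = _nb_draw(rng, scale * lam_cds * cds_len * mod_cds,
                              cfg.nb_dispersion)
            idx = np.repeat(np.arange(n_tx), totals)
            if len(idx):
                codon = (rng.random(len(idx)) * n_codons[idx]).astype(np.int64)
                frame = rng.choice(3, size=len(idx), p=frame_bias)
                parts.append((idx, u5[idx] + 3 * codon + frame))

            # uORF reads, uniform within the planted interval
            if len(uo):
                totals = _nb_draw(rng, scale * lam_uorf * uo_len * mod_uorf,
                                  cfg.nb_dispersion)
                ridx = np.repeat(np.arange(len(uo)), totals)
                if len(ridx):
                    pos = (
                        uo["start"].to_numpy()[ridx]
                        + (rng.random(len(ridx)) * uo_len[ridx]).astype(np.int64)
                    )
                    parts.append((uo_tx_idx[ridx], pos))

            # UTR background
            for lam, length, offset in (
                (lam_u5, u5, np.zeros(n_tx, dtype=np.int64)),
                (lam_u3, u3, u5 + cds_len),
            ):
                totals = _nb_draw(rng, scale * lam * length, cfg.nb_dispersion)
                idx = np.repeat(np.arange(n_tx), totals)
                if len(idx):
                    pos = offset[idx] + (
                        rng.random(len(idx)) * length[idx]
                    ).astype(np.int64)
                    parts.append((idx, pos))

            if parts:
                tx_idx = np.concatenate([p[0] for p in parts])
                psites = np.concatenate([p[1] for p in parts])
            else:  # pragma: no cover - empty library
                tx_idx = np.zeros(0, dtype=int)
                psites = np.zeros(0, dtype=np.int64)
            read_len = rng.choice(
                _READ_LENGTHS, size=len(tx_idx), p=_READ_LENGTH_PROBS
            )
            five_prime = psites - _PSITE_OFFSET
            keep = five_prime >= 0
            df = (
                pd.DataFrame(
                    {
                        "transcript_id": tids[tx_idx[keep]],
                        "position": five_prime[keep],
                        "read_length": read_len[keep],
                        "count": 1,
                    }
                )
                .groupby(["transcript_id", "position", "read_length"], as_index=False)[
                    "count"
                ]
                .sum()
            )
            tables.append(
                FootprintTable(
                    sample_id=sample_id,
                    data=df,
                    coordinate_mode=CoordinateMode.FIVE_PRIME,
                )
            )
            metas.append(
                SampleMeta(
                    sample_id=sample_id,
                    circadian_time=float(t),
                    replicate=rep,
                    condition="WT",
                )
            )
    return tables, metas


def simulate_protein(
    truth: GroundTruth,
    cfg: SimConfig,
    turnover_delay_hours: float = 6.0,
    production_scale: float = 1000.0,
    noise_rel: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Protein copies/cell time course, phase-delayed from the footprints.

    Each transcript's protein series is a cosine with the planted phase
    shifted by ``turnover_delay_hours`` and mesor rescaled by
    ``production_scale`` (copies/cell per unit base expression), with
    multiplicative Gaussian noise of relative SD ``noise_rel``.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    tx = truth.transcripts
    rows = []
    for t in cfg.timepoints:
        mod = _modulation(
            t,
            tx["amplitude"].to_numpy(),
            (tx["phase"].to_numpy() + turnover_delay_hours) % 24.0,
        )
        for rep in range(1, cfg.replicates + 1):
            noise = 1.0 + noise_rel * rng.standard_normal(len(tx))
            vals = np.clip(
                production_scale * tx["base_expr"].to_numpy() * mod * noise, 0.0, None
            )
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": tx["transcript_id"],
                        "circadian_time": t,
                        "replicate": rep,
                        "copies_per_cell": vals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# full dataset emission


def simulate_experiment(cfg: SimConfig, out_dir) -> Path:
    """Write a complete synthetic dataset directory.

    Emits exactly the formats the annotation readers consume: FASTA,
    structure TSV, per-sample footprint TSVs, sample sheet, protein TSV,
    the ground-truth tables, and a config snapshot.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    models, truth = simulate_transcriptome(cfg, rng)
    tables, metas = simulate_footprints(models, truth, cfg, rng)
    protein = simulate_protein(truth, cfg, rng=rng)

    write_fasta(models, out / "transcripts.fa")
    write_structure_table(models, out / "structure.tsv")
    write_sample_sheet(metas, out / "sample_sheet.tsv")
    fp_dir = out / "footprints"
    fp_dir.mkdir(exist_ok=True)
    for table in tables:
        write_footprints(table, fp_dir / f"{table.sample_id}.tsv")
    protein.to_csv(out / "protein.tsv", sep="\t", index=False, float_format="%.6g")
    truth.transcripts.to_csv(
        out / "truth_transcripts.tsv", sep="\t", index=False, float_format="%.10g"
    )
    truth.uorfs.to_csv(
        out / "truth_uorfs.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (out / "simconfig.json").write_text(cfg.to_json() + "\n")
    logger.info("wrote synthetic dataset with %d transcripts to %s",
                cfg.n_transcripts, out)
    return out
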