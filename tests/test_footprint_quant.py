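import numpy as np
import pandas as pd
import pytest

from riborhythm.annotation_io import CoordinateMode, FootprintTable
from riborhythm.footprint_quant import (
    FAIL,
    PASS,
    TOO_SHORT,
    QuantConfig,
    allocate_uorf_reads,
    assign_psites,
    frame_distribution,
    region_quant,
    well_translated,
    well_translated_table,
)
from riborhythm.uorf_scan import UORFRecord

from .conftest import make_model, psite_table


def five_prime_table(rows, sample_id="s1"):
    df = pd.DataFrame(
        rows, columns=["transcript_id", "position", "read_length", "count"]
    )
    return FootprintTable(
        sample_id=sample_id, data=df, coordinate_mode=CoordinateMode.FIVE_PRIME
    )


def uniform_cds_model(n_codons, tid="tx"):
    return make_model("G" * 30, cds_codons=n_codons, utr3_len=30, tid=tid)


class TestAssignPsites:
    def test_offset_arithmetic(self):
        model = uniform_cds_model(60)
        table = five_prime_table([("tx", 100, 29, 7)])
        out = assign_psites(table, QuantConfig(), [model])
        assert out.coordinate_mode == CoordinateMode.PSITE
        assert out.data.iloc[0]["position"] == 112
        assert out.data.iloc[0]["count"] == 7

    def test_out_of_range_length_dropped_and_tallied(self):
        model = uniform_cds_model(60)
        table = five_prime_table([("tx", 100, 20, 3), ("tx", 100, 29, 1)])
        out = assign_psites(table, QuantConfig(), [model])
        assert len(out.data) == 1
        assert out.dropped_length == 3

    def test_psite_mode_is_identity(self):
        table = psite_table([("tx", 5, 2)])
        assert assign_psites(table, QuantConfig(), []) is table

    def test_off_transcript_psites_dropped(self):
        model = uniform_cds_model(10)  # length 90
        table = five_prime_table([("tx", model.length - 5, 30, 2)])
        out = assign_psites(table, QuantConfig(), [model])
        assert out.data.empty
        assert out.dropped_offend == 2


class TestFrameDistribution:
    def test_pure_frame_zero(self):
        model = uniform_cds_model(60)
        rows = [("tx", model.cds_start + 3 * k, 1) for k in range(10)]
        assert frame_distribution(psite_table(rows), [model]) == (1.0, 0.0, 0.0)

    def test_uniform_positions_near_one_third(self, rng):
        model = uniform_cds_model(333)
        pos = rng.integers(model.cds_start, model.cds_end, 10_000)
        rows = (
            pd.DataFrame({"p": pos})
            .value_counts()
            .reset_index()
            .apply(lambda r: ("tx", int(r["p"]), int(r["count"])), axis=1)
            .tolist()
        )
        fracs = frame_distribution(psite_table(rows), [model])
        assert np.allclose(fracs, 1 / 3, atol=0.02)

    def test_planted_bias_recovered(self, rng):
        model = uniform_cds_model(200)
        bias = (0.6, 0.25, 0.15)
        codons = rng.integers(0, 200, 10_000)
        frames = rng.choice(3, 10_000, p=bias)
        pos = model.cds_start + 3 * codons + frames
        counts = pd.Series(pos).value_counts()
        rows = [("tx", int(p), int(c)) for p, c in counts.items()]
        fracs = frame_distribution(psite_table(rows), [model])
        assert np.allclose(fracs, bias, atol=0.02)

    def test_no_cds_reads_undefined(self):
        model = uniform_cds_model(60)
        fracs = frame_distribution(psite_table([("tx", 0, 5)]), [model])
        assert all(np.isnan(f) for f in fracs)


class TestRegionQuant:
    def test_rpkm_formula(self):
        # 100 CDS reads on a 2000-nt CDS with 10M mapped reads -> RPKM 5
        model = make_model("G" * 30, cds_codons=2000 // 3 + 1, utr3_len=30)
        assert model.cds_len == 2001  # nearest multiple of 3
        rows = [("tx", model.cds_start + i, 1) for i in range(100)]
        rq = region_quant(psite_table(rows), [model], mapped_reads=10_000_000)
        got = rq.iloc[0]
        assert got["reads_cds"] == 100
        assert got["rpkm_cds"] == pytest.approx(100 / (2.001 * 10))

    def test_zero_reads_zero_rpkm(self):
        model = uniform_cds_model(60)
        rq = region_quant(psite_table([]), [model], mapped_reads=1000)
        assert rq.iloc[0][["reads_utr5", "reads_cds", "reads_utr3"]].sum() == 0
        assert rq.iloc[0]["rpkm_cds"] == 0.0

    def test_zero_length_region_rpkm_missing(self):
        model = make_model("", cds_codons=10, utr3_len=0)
        rq = region_quant(psite_table([("tx", 0, 1)]), [model], mapped_reads=10)
        assert np.isnan(rq.iloc[0]["rpkm_utr5"])
        assert np.isnan(rq.iloc[0]["rpkm_utr3"])

    def test_scale_invariance(self):
        model = uniform_cds_model(60)
        rows = [("tx", model.cds_start + 3, 5), ("tx", 2, 7)]
        a = region_quant(psite_table(rows), [model], mapped_reads=1_000_000)
        doubled = [(t, p, 2 * c) for t, p, c in rows]
        b = region_quant(psite_table(doubled), [model], mapped_reads=2_000_000)
        for col in ("rpkm_utr5", "rpkm_cds", "rpkm_utr3"):
            assert a.iloc[0][col] == pytest.approx(b.iloc[0][col])

    def test_conservation_of_counts(self, rng):
        model = uniform_cds_model(50)
        pos = rng.integers(0, model.length, 500)
        counts = pd.Series(pos).value_counts()
        rows = [("tx", int(p), int(c)) for p, c in counts.items()]
        table = psite_table(rows)
        rq = region_quant(table, [model])
        assert (
            rq.iloc[0][["reads_utr5", "reads_cds", "reads_utr3"]].sum()
            == table.total_count
        )

    def test_unknown_transcript_errors(self):
        model = uniform_cds_model(50)
        with pytest.raises(KeyError):
            region_quant(psite_table([("who", 0, 1)]), [model])


def window_oracle(per_codon, cfg: QuantConfig):
    """Materialize every window explicitly and take the median."""
    usable = per_codon[
        cfg.head_exclusion_codons : len(per_codon) - cfg.tail_exclusion_codons
    ]
    windows = [
        sum(usable[k : k + cfg.window_codons])
        for k in range(0, len(usable) - cfg.window_codons + 1, cfg.window_codons)
    ]
    if not windows:
        return TOO_SHORT
    return PASS if np.median(windows) >= cfg.min_median_reads else FAIL


class TestWellTranslated:
    def _table_from_codons(self, model, per_codon):
        rows = [
            ("tx", model.cds_start + 3 * k, int(c))
            for k, c in enumerate(per_codon)
            if c
        ]
        return psite_table(rows)

    @pytest.mark.parametrize("reads,verdict", [(2, PASS), (1, FAIL)])
    def test_25_codon_boundary_single_window(self, reads, verdict):
        """A 25-codon CDS has exactly one window: codons 15-19."""
        model = uniform_cds_model(25)
        per_codon = np.zeros(25, dtype=int)
        per_codon[17] = reads
        got, sums = well_translated(
            self._table_from_codons(model, per_codon), model
        )
        assert len(sums) == 1
        assert got == verdict

    def test_24_codons_too_short(self):
        model = uniform_cds_model(24)
        got, sums = well_translated(psite_table([]), model)
        assert got == TOO_SHORT
        assert len(sums) == 0

    def test_all_zero_counts_fail(self):
        model = uniform_cds_model(100)
        got, _ = well_translated(psite_table([]), model)
        assert got == FAIL

    def test_reads_outside_window_region_ignored(self):
        model = uniform_cds_model(25)
        per_codon = np.zeros(25, dtype=int)
        per_codon[:15] = 99  # head-excluded codons
        per_codon[20:] = 99  # tail-excluded codons
        got, _ = well_translated(self._table_from_codons(model, per_codon), model)
        assert got == FAIL

    def test_matches_explicit_window_oracle(self, rng):
        cfg = QuantConfig()
        for _ in range(300):
            n_codons = int(rng.integers(5, 120))
            model = uniform_cds_model(n_codons)
            per_codon = rng.poisson(0.6, n_codons)
            got, _ = well_translated(
                self._table_from_codons(model, per_codon), model, cfg
            )
            assert got == window_oracle(per_codon, cfg)

    def test_monotone_in_added_reads(self, rng):
        """Adding reads can only move FAIL -> PASS, never the reverse."""
        cfg = QuantConfig()
        for _ in range(50):
            n_codons = int(rng.integers(25, 80))
            model = uniform_cds_model(n_codons)
            base = rng.poisson(0.4, n_codons)
            more = base + rng.poisson(0.5, n_codons)
            v1, _ = well_translated(self._table_from_codons(model, base), model, cfg)
            v2, _ = well_translated(self._table_from_codons(model, more), model, cfg)
            assert not (v1 == PASS and v2 == FAIL)

    def test_pooled_table_across_samples(self):
        model = uniform_cds_model(25)
        per_codon = np.zeros(25, dtype=int)
        per_codon[16] = 1
        t1 = self._table_from_codons(model, per_codon)
        t2 = self._table_from_codons(model, per_codon)
        pooled = well_translated_table([t1, t2], [model])
        assert pooled.iloc[0]["verdict"] == PASS  # 1 + 1 = 2 reads pooled
        per_sample = well_translated_table([t1, t2], [model], pool_samples=False)
        assert per_sample.iloc[0]["verdict"] == FAIL


class TestAllocateUorfReads:
    def _uorf(self, start, end, tid="tx"):
        return UORFRecord(
            transcript_id=tid,
            start=start,
            end=end,
            start_codon="ATG",
            cognate_class="canonical",
            distance_d=0,
        )

    def test_interval_containment(self):
        table = psite_table([("tx", 0, 3), ("tx", 5, 4)])
        out = allocate_uorf_reads(table, [self._uorf(0, 6)])
        assert out.iloc[0]["count"] == 7

    def test_half_open_end_excluded(self):
        table = psite_table([("tx", 6, 3)])
        out = allocate_uorf_reads(table, [self._uorf(0, 6)])
        assert out.iloc[0]["count"] == 0

    def test_nested_uorfs_double_count(self):
        table = psite_table([("tx", 4, 2)])
        out = allocate_uorf_reads(
            table, [self._uorf(0, 9), self._uorf(3, 9)]
        ).set_index("uorf_id")
        assert out.loc["tx:0-9", "count"] == 2
        assert out.loc["tx:3-9", "count"] == 2
        assert (out["n_overlapping"] == 1).all()

    def test_rpkm_uses_uorf_length(self):
        table = psite_table([("tx", 0, 10)])
        out = allocate_uorf_reads(table, [self._uorf(0, 6)], mapped_reads=1_000_000)
        assert out.iloc[0]["rpkm"] == pytest.approx(10 / (6 / 1e3) / 1.0)
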