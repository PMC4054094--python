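"""Retrieval-bias simulator: genomes, compaction tracks, biased reads."""

import numpy as np
import pytest
from scipy import stats

import covbias as cb
from covbias.simulate import (
    CNV,
    OVERNIGHT_MIN,
    SimConfig,
    expected_weights,
    make_fixture_suite,
    simulate_compaction,
    simulate_genome,
    simulate_reads,
    simulate_study,
)

SMALL = {"chr1": 400_000}


class TestSimulateGenome:
    def test_no_repeats_when_density_zero(self):
        cfg = SimConfig(chrom_lengths=SMALL, repeat_density=0.0, seed=3)
        _, repeats, _ = simulate_genome(cfg)
        assert repeats["chr1"].shape == (0, 2)

    def test_degenerate_gc_range_hits_half(self):
        cfg = SimConfig(chrom_lengths=SMALL, gc_range=(0.5, 0.5), seed=3)
        genome, _, _ = simulate_genome(cfg)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(0.25 / len(seq))
        assert abs(gc - 0.5) < 3 * se

    def test_isochore_autocorrelation_decays_with_lag(self):
        cfg = SimConfig(chrom_lengths={"chr1": 10_000_000}, isochore_scale=1_000_000,
                        repeat_density=0.0, seed=3)
        _, _, gc_target = simulate_genome(cfg)
        track = gc_target["chr1"]  # 200 bp bins
        bins_10kb = track[: len(track) // 50 * 50].reshape(-1, 50).mean(axis=1)

        def autocorr(x, lag):
            return np.corrcoef(x[:-lag], x[lag:])[0, 1]

        assert autocorr(bins_10kb, 10) > autocorr(bins_10kb, 200)  # 100 kb vs 2 Mb

    def test_deterministic_given_seed(self):
        cfg = SimConfig(chrom_lengths=SMALL, seed=11)
        g1, r1, _ = simulate_genome(cfg)
        g2, r2, _ = simulate_genome(cfg)
        assert g1 == g2 and np.array_equal(r1["chr1"], r2["chr1"])

    def test_repeat_density_approximately_honored(self):
        cfg = SimConfig(chrom_lengths=SMALL, repeat_density=0.25, seed=3)
        _, repeats, _ = simulate_genome(cfg)
        density = (repeats["chr1"][:, 1] - repeats["chr1"][:, 0]).sum() / 400_000
        assert 0.24 <= density <= 0.30


@pytest.fixture(scope="module")
def study_windows():
    cfg = SimConfig(chrom_lengths={"chr1": 1_000_000}, repeat_density=0.1, seed=5)
    genome, repeats, _ = simulate_genome(cfg)
    mask = cb.build_mask(genome, {c: list(map(tuple, iv)) for c, iv in repeats.items()})
    ws = cb.annotate_gc(genome, cb.partition_accessible(mask, 5000))
    return cfg, ws


class TestSimulateCompaction:
    def test_zero_divergence_makes_tissues_identical(self, study_windows):
        cfg, ws = study_windows
        cfg0 = SimConfig(**{**cfg.__dict__, "tissue_divergence": 0.0})
        tracks = simulate_compaction(cfg0, ws)
        np.testing.assert_array_equal(tracks["tissue1"], tracks["tissue2"])

    def test_inter_tissue_correlation_decreases_with_divergence(self, study_windows):
        cfg, ws = study_windows
        corrs = []
        for div in (0.2, 1.0, 3.0):
            c = SimConfig(**{**cfg.__dict__, "tissue_divergence": div})
            tr = simulate_compaction(c, ws)
            corrs.append(np.corrcoef(tr["tissue1"], tr["tissue2"])[0, 1])
        assert corrs[0] > corrs[1] > corrs[2]

    def test_full_gc_coupling_gives_negative_gc_correlation(self, study_windows):
        cfg, ws = study_windows
        c = SimConfig(**{**cfg.__dict__, "compaction_gc_weight": 1.0})
        tr = simulate_compaction(c, ws)
        ok = np.isfinite(ws.gc)
        assert np.corrcoef(tr["tissue1"][ok], ws.gc[ok])[0, 1] < 0

    def test_tracks_bounded_in_unit_interval(self, study_windows):
        cfg, ws = study_windows
        for h in simulate_compaction(cfg, ws).values():
            assert np.all((h >= 0) & (h <= 1))


class TestSimulateReads:
    def test_unbiased_limit_is_uniform_multinomial(self, study_windows):
        cfg, ws = study_windows
        c = SimConfig(**{**cfg.__dict__, "beta0": 0.0, "gc_bias": None,
                         "n_reads": 200_000})
        H = simulate_compaction(c, ws)["tissue1"]
        reads, share = simulate_reads(ws, H, c, tau=30)
        track = cb.count_reads(ws, reads)
        ok = np.isfinite(ws.gc)
        # windows all hold the same accessible bp except a terminal remainder
        full = ok & (ws.table["accessible_bp"].to_numpy() == 5000)
        p = stats.chisquare(track.counts[full]).pvalue
        assert p > 0.01
        np.testing.assert_allclose(share.sum(), 1.0)

    def test_long_lysis_removes_chromatin_dependence(self, study_windows):
        cfg, ws = study_windows
        c = SimConfig(**{**cfg.__dict__, "gc_bias": None, "n_reads": 300_000})
        H = simulate_compaction(c, ws)["tissue1"]
        reads_short, _ = simulate_reads(ws, H, c, tau=0, stream=0)
        reads_long, _ = simulate_reads(ws, H, c, tau=1e9, stream=1)
        t_short = cb.count_reads(ws, reads_short)
        t_long = cb.count_reads(ws, reads_long)
        ok = np.isfinite(ws.gc)
        r_short = np.corrcoef(t_short.counts[ok], H[ok])[0, 1]
        r_long = np.corrcoef(t_long.counts[ok], H[ok])[0, 1]
        n = ok.sum()
        assert r_short < -0.5  # strong bias at tau = 0
        assert abs(r_long) < 3 / np.sqrt(n)  # sampling noise only

    def test_planted_copy_factor_recovered_in_expectation(self, study_windows):
        cfg, ws = study_windows
        cnv = CNV("chr1", 200_000, 400_000, 1.10, "A")
        c = SimConfig(**{**cfg.__dict__, "beta0": 0.0, "gc_bias": None,
                         "cnv_list": (cnv,), "n_reads": 400_000})
        H = simulate_compaction(c, ws)["tissue1"]
        reads, _ = simulate_reads(ws, H, c, tau=30, strain="A")
        track = cb.count_reads(ws, reads)
        tbl = ws.table
        full = np.isfinite(ws.gc) & (tbl["accessible_bp"].to_numpy() == 5000)
        inside = full & (tbl["start"] >= 200_000) & (tbl["end"] <= 400_000)
        outside = full & ~inside
        m_out = track.counts[outside].mean()
        ratio = track.counts[inside].mean() / m_out
        se = np.sqrt(1 / track.counts[inside].sum() + 1 / track.counts[outside].sum()) * 1.10
        assert ratio == pytest.approx(1.10, abs=3 * max(se, 0.01))

    def test_reads_fall_in_accessible_sequence(self, study_windows):
        cfg, ws = study_windows
        H = simulate_compaction(cfg, ws)["tissue1"]
        reads, _ = simulate_reads(ws, H, cfg, tau=30, n_reads=20_000)
        acc = np.zeros(ws.mask.chrom_lengths["chr1"], dtype=bool)
        for s, e in ws.mask.accessible["chr1"]:
            acc[s:e] = True
        assert acc[reads.positions["chr1"]].all()

    def test_negative_lysis_time_rejected(self, study_windows):
        cfg, ws = study_windows
        H = simulate_compaction(cfg, ws)["tissue1"]
        with pytest.raises(ValueError, match="lysis"):
            simulate_reads(ws, H, cfg, tau=-1)


class TestBiasIdentifiability:
    def test_regression_recovers_minus_beta(self, study_windows):
        # log expected-normalized count vs H has slope -beta(tau)
        cfg, ws = study_windows
        for beta in (0.2, 0.5, 1.0):
            c = SimConfig(**{**cfg.__dict__, "beta0": beta, "gc_bias": None})
            H = simulate_compaction(c, ws)["tissue1"]
            w = expected_weights(c, ws, H, tau=0)
            ok = w > 0
            slope = np.polyfit(H[ok], np.log(w[ok]), 1)[0]
            assert slope == pytest.approx(-beta, rel=1e-6)


class TestFixtureSuite:
    def test_tiny_preset_contract(self, tmp_path):
        out = make_fixture_suite("tiny", tmp_path / "fx")
        assert (out / "genome.fa").exists() and (out / "manifest.yaml").exists()
        genome = {}
        import covbias.io as cio
        genome = cio.read_fasta(out / "genome.fa")
        assert sum(map(len, genome.values())) <= 2_000_000

    def test_lysis_series_has_one_library_per_timepoint(self, tmp_path):
        import yaml
        out = make_fixture_suite("lysis-series", tmp_path / "fx")
        manifest = yaml.safe_load((out / "manifest.yaml").read_text())
        names = manifest["libraries"]
        for label in ("10min", "30min", "60min", "120min", "ON"):
            assert any(label in n for n in names)
        assert manifest["beta"]["tissue1_ON"] < manifest["beta"]["tissue1_10min"]

    def test_two_strain_preset_lists_planted_cnvs(self, tmp_path):
        import covbias.io as cio
        out = make_fixture_suite("two-strain-cnv", tmp_path / "fx")
        cnv = cio.read_track_tsv(out / "truth" / "cnv.tsv")
        assert set(cnv["copy_factor"]) == {1.5, 0.5}

    def test_byte_identical_across_runs(self, tmp_path):
        a = make_fixture_suite("tiny", tmp_path / "a")
        b = make_fixture_suite("tiny", tmp_path / "b")
        assert (a / "manifest.yaml").read_text() == (b / "manifest.yaml").read_text()
        assert (a / "genome.fa").read_bytes() == (b / "genome.fa").read_bytes()
        assert (a / "reads" / "tissue1_t120.bed").read_bytes() == (
            b / "reads" / "tissue1_t120.bed").read_bytes()

    def test_unknown_preset_lists_options(self, tmp_path):
        with pytest.raises(ValueError, match="tiny"):
            make_fixture_suite("nope", tmp_path)
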