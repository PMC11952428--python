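"""Generative model: reference construction, accessibility, fiber simulation."""

import numpy as np
import pandas as pd
import pytest

from fibermod.fiber_sim import (FiberSimConfig, accessibility,
                                expected_amplitude, false_positive_rate,
                                make_reference, simulate_dataset,
                                simulate_fiber, true_positive_rate)
from fibermod.modbam_io import revcomp


def small_config(**kw):
    base = dict(seed=3, genome_length=120_000, n_sites=10,
                site_spacing=10_000, coverage=12, frag_len_mean=8_000,
                frag_len_sd=1_000)
    base.update(kw)
    return FiberSimConfig(**base)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            FiberSimConfig(p_bound=1.5).validate()
        with pytest.raises(ValueError):
            FiberSimConfig(nrl=100, core_len=147).validate()
        with pytest.raises(ValueError):
            FiberSimConfig(coverage=0).validate()
        with pytest.raises(ValueError):
            FiberSimConfig(motif="ACGTX").validate()
        with pytest.raises(ValueError):
            FiberSimConfig(n_sites=100, site_spacing=10_000,
                           genome_length=600_000).validate()


class TestReference:
    def test_sites_planted_at_regular_spacing_alternating_strands(self):
        cfg = small_config()
        contigs, sites = make_reference(cfg)
        assert len(sites) == 10
        assert sites.strand.tolist() == ["+", "-"] * 5
        genome = contigs["chr_sim"]
        assert len(genome) == cfg.genome_length
        starts = sites.start.to_numpy()
        assert np.all(np.diff(starts) == cfg.site_spacing)

    def test_diploid_contigs_identical_with_same_site_offsets(self):
        contigs, sites = make_reference(small_config(diploid=True))
        assert set(contigs) == {"chr_sim_MATERNAL", "chr_sim_PATERNAL"}
        assert contigs["chr_sim_MATERNAL"] == contigs["chr_sim_PATERNAL"]
        mat = sites[sites.contig == "chr_sim_MATERNAL"].start.tolist()
        pat = sites[sites.contig == "chr_sim_PATERNAL"].start.tolist()
        assert mat == pat

    def test_planted_motifs_recovered_by_scanner(self):
        from fibermod.regions import scan_motif

        cfg = small_config(motif="CCGCGAGGTGGCAG")
        contigs, sites = make_reference(cfg)
        hits = scan_motif(contigs, cfg.motif)
        planted = set(zip(sites.start, sites.strand))
        found = set(zip(hits.start, hits.strand))
        assert planted <= found


class TestAccessibility:
    def test_motif_footprint_blocks_center(self):
        cfg = FiberSimConfig()
        assert accessibility(0, bound=True, config=cfg) == 0.0

    def test_first_core_blocks_interior(self):
        # footprint + core_len/2 lies inside the first phased core
        cfg = FiberSimConfig()
        d = cfg.footprint_halfwidth + cfg.core_len / 2
        assert accessibility(d, bound=True, config=cfg) == 0.0

    def test_first_linker_accessible(self):
        cfg = FiberSimConfig()
        linker = cfg.nrl - cfg.core_len
        d = cfg.footprint_halfwidth + linker / 2
        assert accessibility(d, bound=True, config=cfg) == 1.0

    def test_unbound_phase_tiling(self):
        cfg = FiberSimConfig()
        # core occupies [phase, phase + core_len) modulo NRL
        assert accessibility(10.0, bound=False, config=cfg,
                             phase_offset=0.0) == 0.0
        assert accessibility(cfg.core_len + 1.0, bound=False, config=cfg,
                             phase_offset=0.0) == 1.0

    def test_mean_bound_accessibility_oscillates_at_nrl(self, rng):
        cfg = FiberSimConfig()
        d = np.arange(-1000, 1001, dtype=float)
        acc = np.zeros_like(d)
        n = 3000
        for _ in range(n):
            acc += accessibility(d, bound=True, config=cfg, rng=rng)
        acc /= n
        # autocorrelation of the mean-removed flank profile peaks near NRL
        flank = acc[1000 + 250:]
        flank = flank - flank.mean()
        ac = np.correlate(flank, flank, mode="full")[flank.size - 1:]
        lag = np.argmax(ac[120:300]) + 120
        assert abs(lag - cfg.nrl) <= 15

    def test_heavy_jitter_destroys_oscillation_roughly_preserves_mean(self, rng):
        # index-scaled jitter eventually scatters cores out of any finite
        # window, so the limit is tested at heavy (5x default) jitter: the
        # NRL oscillation collapses while mean accessibility moves little
        cfg = FiberSimConfig()
        noisy = cfg.replace(jitter_sd=80.0)
        d = np.arange(60, 1100, dtype=float)
        n = 2000
        acc_ref = np.mean([accessibility(d, bound=True, config=cfg, rng=rng)
                           for _ in range(n)], axis=0)
        acc_jit = np.mean([accessibility(d, bound=True, config=noisy, rng=rng)
                           for _ in range(n)], axis=0)

        def osc_amplitude(a, period=190):
            trend = np.convolve(a, np.ones(period + 1) / (period + 1),
                                mode="same")
            return (a - trend)[period:-period].std()

        assert osc_amplitude(acc_jit) < 0.2 * osc_amplitude(acc_ref)
        # heavily jittered cores overlap and scatter, so accessibility rises
        # but stays far from fully open or fully closed
        assert 0.2 < acc_jit.mean() < 0.7


class TestScoreModel:
    def test_rates_decrease_with_threshold(self):
        cfg = FiberSimConfig()
        tprs = [true_positive_rate(t, cfg) for t in (0, 100, 225, 250)]
        assert tprs[0] == 1.0
        assert tprs == sorted(tprs, reverse=True)
        assert false_positive_rate(225, cfg) < 1e-6

    def test_expected_amplitude_combines_rates(self):
        cfg = FiberSimConfig()
        amp = expected_amplitude(cfg, 225)
        assert amp == pytest.approx(
            cfg.A_teth * true_positive_rate(225, cfg)
            + (1 - cfg.A_teth) * false_positive_rate(225, cfg))


class TestSimulateFiber:
    def _fiber(self, cfg, rng, bound=True, strand="+"):
        contigs, sites = make_reference(cfg)
        genome = contigs["chr_sim"]
        seq_arr = np.frombuffer(genome.encode(), dtype="S1")
        center = (sites.iloc[2].start + sites.iloc[2].end) // 2
        return simulate_fiber(genome, seq_arr, center - 3000, center + 3000,
                              strand, [center], [bound], None, cfg, rng,
                              read_id="f0"), center

    def test_null_condition_scores_below_threshold(self, rng):
        cfg = small_config(A_teth=0.0, bg_rate=0.0)
        fiber, _ = self._fiber(cfg, rng)
        assert not fiber.a_truth.any()
        from fibermod.modbam_io import binarize

        assert binarize(fiber.a_scores, 225).mean() < 0.01

    def test_bound_fiber_methylates_only_accessible_adenines(self, rng):
        cfg = small_config(jitter_sd=0.0, bg_rate=0.0)
        fiber, center = self._fiber(cfg, rng)
        d = fiber.a_positions[fiber.a_truth] - center
        acc = accessibility(d, bound=True, config=cfg)
        assert np.all(acc == 1.0)

    def test_linker_methylation_matches_closed_form(self, rng):
        # at the first linker the per-adenine modified fraction is
        # A_teth * exp(-lam * d) within binomial error over many fibers
        cfg = small_config(jitter_sd=0.0, bg_rate=0.0, p_bound=1.0)
        linker_lo = cfg.footprint_halfwidth
        linker_hi = cfg.footprint_halfwidth + (cfg.nrl - cfg.core_len)
        hits = total = 0
        expect_num = expect_den = 0.0
        for _ in range(400):
            fiber, center = self._fiber(cfg, rng)
            d = np.abs(fiber.a_positions - center)
            in_linker = (d >= linker_lo) & (d < linker_hi)
            hits += int(fiber.a_truth[in_linker].sum())
            total += int(in_linker.sum())
            expect_num += float(
                (cfg.A_teth * np.exp(-cfg.lam_teth * d[in_linker])).sum())
            expect_den += int(in_linker.sum())
        observed = hits / total
        expected = expect_num / expect_den
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(observed - expected) < 4 * se

    def test_minus_strand_fiber_calls_sit_on_reference_t(self, rng):
        cfg = small_config()
        contigs, sites = make_reference(cfg)
        genome = contigs["chr_sim"]
        fiber, _ = self._fiber(cfg, rng, strand="-")
        bases = {genome[p] for p in fiber.a_positions}
        assert bases == {"T"}
        cpg_bases = {genome[p - 1:p + 1] for p in fiber.cpg_positions}
        assert cpg_bases == {"CG"}


class TestSimulateDataset:
    def test_read_count_matches_coverage(self, small_sim):
        cfg, out = small_sim
        expected = cfg.coverage * cfg.genome_length / cfg.frag_len_mean
        assert abs(out["n_reads"] - expected) <= 1

    def test_same_seed_identical_truth(self, tmp_path):
        cfg = small_config(coverage=4)
        t1 = simulate_dataset(cfg, "target", tmp_path / "a")
        t2 = simulate_dataset(cfg, "target", tmp_path / "b")
        assert (t1["truth"].read_bytes() == t2["truth"].read_bytes())

    def test_igg_condition_has_no_bound_fibers(self, tmp_path):
        cfg = small_config(coverage=4)
        out = simulate_dataset(cfg, "igg", tmp_path / "igg")
        truth = pd.read_csv(out["truth"], sep="\t")
        assert (truth.bound == 0).all()

    def test_truth_conservation_against_emitted_calls(self, small_sim):
        import pysam

        from fibermod.modbam_io import decode_read

        _, out = small_sim
        truth = pd.read_csv(out["truth"], sep="\t",
                            keep_default_na=False).set_index("read_id")
        with pysam.AlignmentFile(str(out["bam"]), "rb") as bam:
            checked = 0
            for aln in bam.fetch():
                rec = decode_read(aln)
                row = truth.loc[rec.read_id]
                emitted_a = {c.ref_pos for c in rec.calls if c.mod_code == "a"}
                truth_a = {int(p) for p in str(row.a_meth_pos).split(",")
                           if p}
                assert truth_a <= emitted_a
                assert len([c for c in rec.calls if c.mod_code == "a"]) \
                    == row.n_a_calls
                checked += 1
                if checked >= 25:
                    break
        assert checked == 25

    def test_invalid_condition_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="condition"):
            simulate_dataset(small_config(), "chip", tmp_path)
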