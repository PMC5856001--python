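"""Synthetic genome generator: GC/repeat targets, mark planting, motifs, determinism."""

import numpy as np
import pytest

from dsbpred import (
    composition,
    make_shape_table,
    occupancy_features,
    odds_ratio,
    scan_motif,
)
from dsbpred.enrichment import ContingencyTable2x2
from dsbpred.motifs import MotifModel, revcomp
from dsbpred.simulate import (
    MarkSpec,
    MotifSpec,
    SimulationConfig,
    generate_genome,
    plant_motifs,
    simulate_dataset,
)


class TestGenerateGenome:
    def test_realized_gc_close_to_target(self):
        cfg = SimulationConfig(seed=3, n_chroms=1, chrom_length=1_000_000, n_dsb=100)
        genome = generate_genome(cfg)
        comp = composition(genome.fetch("chr1", 0, 1_000_000))
        assert comp.gc == pytest.approx(0.41, abs=0.01)

    def test_repeat_fraction_realized(self):
        cfg = SimulationConfig(
            seed=3, n_chroms=1, chrom_length=500_000, n_dsb=100, repeat_fraction=0.3
        )
        genome = generate_genome(cfg)
        comp = composition(genome.fetch("chr1", 0, 500_000))
        assert comp.repeat == pytest.approx(0.3, abs=0.02)

    def test_zero_repeat_fraction_means_no_lowercase(self):
        cfg = SimulationConfig(
            seed=5, n_chroms=1, chrom_length=100_000, n_dsb=20, repeat_fraction=0.0
        )
        genome = generate_genome(cfg)
        assert genome.fetch("chr1", 0, 100_000).isupper()

    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=9, n_chroms=1, chrom_length=100_000, n_dsb=20)
        a = generate_genome(cfg).fetch("chr1", 0, 100_000)
        b = generate_genome(cfg).fetch("chr1", 0, 100_000)
        assert a == b

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, gc_target=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_chroms=1, chrom_length=100_000, n_dsb=5000)


class TestPlantDsbAndMarks:
    def test_realized_frequencies_match_specification(self, sim):
        truth = sim["truth"]
        n = len(truth.dsb_sites)
        for mark in sim["cfg"].marks:
            f_pos, f_neg = truth.realized_frequencies[mark.name]
            for f, p in ((f_pos, mark.p_pos), (f_neg, mark.p_neg)):
                sd = np.sqrt(p * (1 - p) / n)
                assert abs(f - p) <= 3 * sd + 1e-12

    def test_occupancy_recovers_planted_frequencies(self, sim):
        """Re-deriving presence from emitted peaks agrees with ground truth."""
        truth = sim["truth"]
        pos = occupancy_features(truth.dsb_sites, truth.mark_peaks)
        for mark in sim["cfg"].marks:
            f_pos, _ = truth.realized_frequencies[mark.name]
            assert (pos[mark.name] > 0).mean() >= f_pos - 1e-12

    def test_null_mark_gives_unit_odds_ratio(self, null_sim):
        truth = null_sim["truth"]
        pos = occupancy_features(truth.dsb_sites, truth.mark_peaks)
        neg = occupancy_features(truth.control_sites, truth.mark_peaks)
        a = int((pos["null_mark"] > 0).sum())
        c = int((neg["null_mark"] > 0).sum())
        t = ContingencyTable2x2(a, len(pos) - a, c, len(neg) - c)
        assert 0.5 < odds_ratio(t) < 2.0

    def test_sites_do_not_overlap(self, sim):
        sites = list(sim["truth"].dsb_sites) + list(sim["truth"].control_sites)
        sites.sort(key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(sites, sites[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_site_sizes_within_configured_range(self, sim):
        lo, hi = sim["cfg"].site_size_range
        sizes = [iv.length for iv in sim["truth"].dsb_sites]
        assert min(sizes) >= lo and max(sizes) <= hi
        assert np.median(sizes) == pytest.approx(391, rel=0.15)

    def test_deterministic_ground_truth(self):
        cfg = SimulationConfig(seed=31, n_chroms=1, chrom_length=300_000, n_dsb=150)
        _, t1 = simulate_dataset(cfg)
        _, t2 = simulate_dataset(cfg)
        assert t1.dsb_sites == t2.dsb_sites
        assert t1.control_sites == t2.control_sites
        assert t1.realized_frequencies == t2.realized_frequencies


CONSENSUS = "GCGCCATCTAGTGGCAGGA"  # 19-mer, CTCF-like width


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        seed=41,
        n_chroms=1,
        chrom_length=600_000,
        n_dsb=300,
        marks=[],
        motifs=[MotifSpec(CONSENSUS, "CTCF_motif", target_or=25.0)],
    )
    genome, truth = simulate_dataset(cfg)
    return genome, truth


class TestPlantMotifs:
    def scan_presence(self, genome, sites):
        m = MotifModel(
            "M1",
            "CTCF_motif",
            np.array(
                [[10.0 if c == b else 0.0 for c in CONSENSUS] for b in "ACGT"]
            ),
        )
        present = []
        for iv in sites:
            seq = genome.fetch(iv.chrom, iv.start, iv.end)
            present.append(len(scan_motif(seq, m, min_rel_score=0.95)) > 0)
        return np.array(present)

    def test_realized_or_within_twofold_of_target(self, planted):
        genome, truth = planted
        pos = self.scan_presence(genome, truth.dsb_sites)
        neg = self.scan_presence(genome, truth.control_sites)
        t = ContingencyTable2x2(
            int(pos.sum()), int((~pos).sum()), int(neg.sum()), int((~neg).sum())
        )
        realized = odds_ratio(t, haldane=True)
        assert 25.0 / 2 <= realized <= 25.0 * 2

    def test_recorded_counts_match_bookkeeping(self, planted):
        _, truth = planted
        assert truth.motif_counts is not None
        assert (truth.motif_counts["CTCF_motif"] >= 0).all()
        assert truth.motif_counts["CTCF_motif"].sum() > 0
        assert "CTCF_motif" in truth.realized_motif_or

    def test_null_motif_or_near_one(self):
        cfg = SimulationConfig(
            seed=43,
            n_chroms=1,
            chrom_length=600_000,
            n_dsb=300,
            marks=[],
            motifs=[MotifSpec(CONSENSUS, "null_motif", target_or=1.0, baseline_rate=0.2)],
        )
        _, truth = simulate_dataset(cfg)
        assert truth.realized_motif_or["null_motif"] == pytest.approx(1.0, abs=0.8)


class TestShapeTableStandIn:
    def test_complete_and_symmetric(self):
        table = make_shape_table(seed=2)
        assert len(table) == 1024
        for pent in ("AACGT", "GGGTA", "ACGTA"):
            assert np.allclose(table.lookup(pent), table.lookup(revcomp(pent)))

    def test_deterministic_under_seed(self):
        a, b = make_shape_table(7), make_shape_table(7)
        assert all(np.array_equal(a.lookup(p), b.lookup(p)) for p in a.entries)

    def test_different_seed_changes_values(self):
        a, b = make_shape_table(1), make_shape_table(2)
        assert any(not np.array_equal(a.lookup(p), b.lookup(p)) for p in a.entries)
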