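"""Synthetic-genome generator: determinism, planted structure, invariants."""

import numpy as np
import pandas as pd
import pytest

import colocmap as cm
from colocmap.simulate import (
    FeatureSpec,
    HotspotPlan,
    SimConfig,
    default_config,
    plant_hotspots,
    simulate_dataset,
    simulate_genome,
    simulate_tracks,
    write_dataset,
)

MARKERS = (
    FeatureSpec("SNPdb", "count", 200.0, latent_cv=0.2),
    FeatureSpec("SNP1K", "count", 200.0, latent_cv=0.2),
    FeatureSpec("CNVG", "count", 100.0, latent_cv=0.2),
    FeatureSpec("RecH", "intensity", 50.0, length_mean_bp=2_000.0, score_scale=0.5),
)


def small_cfg(seed=1, **kw):
    defaults = dict(
        seed=seed,
        chromosome_lengths=(10_000_000,),
        W=500_000,
        features=(FeatureSpec("A", "count", 50.0),),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateGenome:
    def test_toy_genome_window_count_and_zones(self):
        layout, gaps, truth = simulate_genome(small_cfg())
        assert len(truth.zone) == 20
        assert len(gaps) == 0
        assert set(truth.zone) <= {"Genic", "Proximal", "Distal"}

    def test_deterministic_given_seed(self):
        cfg = small_cfg(seed=9, n_gap_windows=2)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1].intervals, b[1].intervals)
        np.testing.assert_array_equal(a[2].zone, b[2].zone)
        np.testing.assert_array_equal(a[2].kept, b[2].kept)

    def test_different_seeds_differ(self):
        za = simulate_genome(small_cfg(seed=1))[2].zone
        zb = simulate_genome(small_cfg(seed=2))[2].zone
        assert not np.array_equal(za, zb)

    def test_zone_mix_matches_plan_within_two_windows(self):
        cfg = small_cfg(chromosome_lengths=(250_000_000, 250_000_000))
        _, _, truth = simulate_genome(cfg)
        n = len(truth.zone)
        assert n == 1_000
        for zone, frac in dict(cfg.zone_fractions).items():
            assert abs(np.sum(truth.zone == zone) - frac * n) <= 2

    def test_gap_windows_removed_from_kept(self):
        cfg = small_cfg(n_gap_windows=3)
        _, gaps, truth = simulate_genome(cfg)
        assert truth.kept.sum() == 17
        assert len(gaps) == 3

    def test_invalid_zone_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_cfg(zone_fractions=(("Genic", 0.5), ("Proximal", 0.2), ("Distal", 0.2)))


class TestSimulateTracks:
    def test_intervals_within_chromosome_and_outside_gaps(self):
        cfg = small_cfg(n_gap_windows=4, features=MARKERS)
        layout, gaps, truth = simulate_genome(cfg)
        tracks = simulate_tracks(cfg, truth)
        gap_ids = np.flatnonzero(~truth.kept)
        for t in tracks:
            t.validate_against(layout)
            widx = t.intervals["start"].to_numpy() // cfg.W
            assert not np.isin(widx, gap_ids).any()
            # no interval crosses a window boundary by construction
            assert ((t.intervals["end"] - 1) // cfg.W == widx).all()

    def test_zone_fold_recovered_in_windowed_means(self):
        cfg = small_cfg(
            chromosome_lengths=(500_000_000,),
            features=(FeatureSpec("G", "count", 50.0, (("Genic", 4.0),)),),
        )
        layout, _, truth = simulate_genome(cfg)
        tracks = simulate_tracks(cfg, truth)
        grid = cm.make_windows(layout, cfg.W)
        levels = cm.build_matrix(grid, tracks)["G"]
        in_zone = levels[truth.kept_zone == "Genic"].mean()
        out_zone = levels[truth.kept_zone != "Genic"].mean()
        assert in_zone / out_zone == pytest.approx(4.0, rel=0.10)

    @pytest.mark.parametrize("target", [-0.5, 0.0, 0.5, 0.9])
    def test_planted_pairwise_correlation_recovered(self, target):
        """Planted r recovered within +/-0.05 at 5,000 windows."""
        corrs = (("A", "B", target),) if target != 0 else ()
        cfg = SimConfig(
            seed=31,
            chromosome_lengths=(2_500_000_000,),
            W=500_000,
            features=(FeatureSpec("A", "count", 200.0), FeatureSpec("B", "count", 200.0)),
            correlations=corrs,
        )
        layout, _, truth = simulate_genome(cfg)
        tracks = simulate_tracks(cfg, truth)
        grid = cm.make_windows(layout, cfg.W)
        m = cm.build_matrix(grid, tracks)
        est = np.corrcoef(m["A"], m["B"])[0, 1]
        assert est == pytest.approx(target, abs=0.05)

    def test_infeasible_correlation_plan_rejected(self):
        cfg = small_cfg(
            features=(
                FeatureSpec("A", "count", 50.0),
                FeatureSpec("B", "count", 50.0),
                FeatureSpec("C", "count", 50.0),
            ),
            correlations=(("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", -0.9)),
        )
        layout, _, truth = simulate_genome(cfg)
        with pytest.raises(ValueError, match="not PSD"):
            simulate_tracks(cfg, truth)


class TestPlantHotspots:
    def hotspot_cfg(self, seed=5, **plan_kw):
        plan = dict(n_single=0, n_double=0, n_triple=50)
        plan.update(plan_kw)
        return SimConfig(
            seed=seed,
            chromosome_lengths=(250_000_000, 250_000_000),
            W=500_000,
            features=MARKERS,
            hotspots=HotspotPlan(**plan),
        )

    def test_fold_one_leaves_tracks_unchanged(self):
        cfg = self.hotspot_cfg(fold=1.0)
        layout, _, truth = simulate_genome(cfg)
        tracks = simulate_tracks(cfg, truth)
        planted, truth = plant_hotspots(cfg, tracks, truth)
        for before, after in zip(tracks, planted):
            if before.feature_name == "RecH":
                continue  # recombination scores are still elevated in triples
            pd.testing.assert_frame_equal(before.intervals, after.intervals)

    def test_high_fold_windows_dominate(self):
        cfg = self.hotspot_cfg(n_triple=5)
        layout, _, truth = simulate_genome(cfg)
        tracks, truth = plant_hotspots(cfg, simulate_tracks(cfg, truth), truth)
        grid = cm.make_windows(layout, cfg.W)
        m = cm.build_matrix(grid, tracks)
        v = m["SNPdb"]
        top5 = set(np.argsort(v)[-5:].tolist())
        assert top5 == truth.hotspots["SNPdb"]

    def test_end_to_end_triple_recovery_is_exact(self):
        """Full pipeline on planted data: top-5% calling recovers exactly the
        planted triple-hotspot set (fold 10, 1,000 windows, 50 planted)."""
        cfg = self.hotspot_cfg()
        layout, _, truth = simulate_genome(cfg)
        tracks, truth = plant_hotspots(cfg, simulate_tracks(cfg, truth), truth)
        grid = cm.make_windows(layout, cfg.W)
        m = cm.build_matrix(grid, tracks)
        sets = [cm.call_hotspots(m, f, q=0.05) for f in ("SNPdb", "SNP1K", "CNVG")]
        ov = cm.overlap_hotspots(sets)
        assert ov.triple == truth.triple_hotspots  # precision = recall = 1

    def test_recombination_p_decreases_with_planted_fold(self):
        """Higher planted recombination elevation gives stronger rate-test evidence."""
        ps = []
        for fold in (1.5, 3.0, 6.0):
            cfg = self.hotspot_cfg(seed=13, recomb_fold=fold)
            layout, _, truth = simulate_genome(cfg)
            tracks, truth = plant_hotspots(cfg, simulate_tracks(cfg, truth), truth)
            grid = cm.make_windows(layout, cfg.W)
            m = cm.build_matrix(grid, tracks)
            rec = m["RecH"]
            rt = cm.rate_test(rec, rec[sorted(truth.triple_hotspots)])
            ps.append(rt.p)
        assert ps[0] > ps[1] > ps[2]


class TestDatasetRoundTrip:
    def test_write_dataset_is_byte_identical_across_runs(self, tmp_path):
        cfg = default_config(seed=3, n_windows=60)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        for name in ["genome.chrom.sizes", "gaps.bed", "truth.json", "genes.bed",
                     "gene_sets.tsv", "tracks_manifest.tsv"]:
            fa, fb = tmp_path / "a" / name, tmp_path / "b" / name
            if name == "tracks_manifest.tsv":
                # manifest embeds output paths; compare structure only
                assert len(fa.read_text().splitlines()) == len(fb.read_text().splitlines())
                continue
            assert fa.read_bytes() == fb.read_bytes(), name
        ta = sorted((tmp_path / "a" / "tracks").iterdir())
        tb = sorted((tmp_path / "b" / "tracks").iterdir())
        assert [p.name for p in ta] == [p.name for p in tb]
        for pa, pb in zip(ta, tb):
            assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_emitted_files_load_through_the_readers(self, tmp_path):
        cfg = default_config(seed=3, n_windows=60)
        paths = write_dataset(simulate_dataset(cfg), tmp_path)
        layout = cm.read_chrom_sizes(paths["layout"])
        gaps = cm.read_gap_track(paths["gaps"], layout=layout)
        man = pd.read_csv(paths["manifest"], sep="\t")
        tracks = [
            cm.read_feature_track(r["path"], r["name"], r["mode"], layout=layout)
            for _, r in man.iterrows()
        ]
        assert len(tracks) == 35
        grid = cm.filter_gap_windows(cm.make_windows(layout, cfg.W), gaps)
        m = cm.build_matrix(grid, tracks)
        assert m.n_windows == grid.n_kept
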