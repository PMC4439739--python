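import math

import numpy as np
import pytest
from scipy.special import erf

from micoskit.apms import write_stats_table
from micoskit.compass import filter_hcips, score_interactions
from micoskit.complexome import detect_shift, protein_fraction_ratios
from micoskit.goldmap import nearest_cj_distance
from micoskit.network import BaitHcips, build_network
from micoskit.simulate import (
    ApmsSimConfig,
    ComplexomeSimConfig,
    ComplexSpec,
    GoldSimConfig,
    PlantedInteraction,
    micos_knockdown_config,
    simulate_apms,
    simulate_complexome,
    simulate_micrograph,
)

SEG = [np.array([[0.0, 0.0], [4000.0, 0.0]])]


def planted_panel(n=10, multiplier=5.0):
    return [
        PlantedInteraction(bait=f"BAIT{i + 1:03d}", prey=f"PLANT{i + 1:02d}",
                           multiplier=multiplier)
        for i in range(n)
    ]


class TestSimulateApms:
    def test_no_planted_gives_empty_truth(self):
        table, truth = simulate_apms(ApmsSimConfig(k_baits=5, n_background_preys=30, seed=1))
        assert truth == []
        assert table.k == 5

    def test_same_seed_byte_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            cfg = ApmsSimConfig(k_baits=8, n_background_preys=40,
                                planted=planted_panel(2), seed=99)
            table, _ = simulate_apms(cfg)
            p = tmp_path / f"{run}.tsv"
            write_stats_table(table, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_planted_pairs_score_above_normalizer(self):
        """Rare (frequency 1/k) planted preys at 5x background APSM score in
        the top WD tail: full recall at NWD > 1 on a 10-plant fixture."""
        cfg = ApmsSimConfig(planted=planted_panel(10), seed=7)
        table, truth = simulate_apms(cfg)
        hcips = filter_hcips(score_interactions(table))
        pred = {(s.bait, s.prey) for s in hcips}
        assert set(truth) <= pred

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_apms(ApmsSimConfig(k_baits=1, seed=0))

    def test_planted_collision_rejected(self):
        bad = [PlantedInteraction(bait="BAIT001", prey="PREY0001")]
        with pytest.raises(ValueError, match="collides"):
            simulate_apms(ApmsSimConfig(planted=bad, seed=0))

    def test_end_to_end_network_precision(self):
        """Scoring + filtering + network assembly on a 10-bait simulation
        recovers only planted edges (precision >= 0.9)."""
        cfg = ApmsSimConfig(k_baits=10, n_background_preys=100,
                            planted=planted_panel(10), seed=3)
        table, truth = simulate_apms(cfg)
        hcips = filter_hcips(score_interactions(table))
        entries = [
            BaitHcips(bait=b, cell_line="sim",
                      hcips=[s for s in hcips if s.bait == b])
            for b in table.baits
        ]
        net = build_network(entries, include_isolated_baits=False)
        edges = {frozenset(e) for e in net.graph.edges}
        true_edges = {frozenset(t) for t in truth}
        assert edges, "no edges recovered"
        precision = len(edges & true_edges) / len(edges)
        assert precision >= 0.9


class TestSimulateComplexome:
    def test_null_scenario_calls_no_change(self):
        misses = total = 0
        for seed in range(10):
            cfg = micos_knockdown_config(null=True, seed=seed)
            quants, truth = simulate_complexome(cfg)
            assert set(truth.values()) == {"no_change"}
            prof = protein_fraction_ratios(quants, cfg.calibration)
            for call in detect_shift(prof, cfg.calibration):
                total += 1
                misses += call.call != "no_change"
        assert misses / total <= 0.05

    def test_shift_analog_detected(self):
        cfg = micos_knockdown_config(seed=0)
        quants, truth = simulate_complexome(cfg)
        assert truth["MIC60"] == "subcomplex_shift"
        assert truth["MIC10"] == "degraded"
        assert truth["SAMM50"] == "no_change"
        prof = protein_fraction_ratios(quants, cfg.calibration)
        calls = {c.protein: c.call for c in detect_shift(prof, cfg.calibration)}
        assert calls["MIC60"] == "subcomplex_shift"
        assert calls["MIC10"] == "degraded"

    def test_degraded_total_ratio_near_programmed_factor(self):
        totals = []
        for seed in range(20):
            cfg = micos_knockdown_config(seed=seed)
            quants, _ = simulate_complexome(cfg)
            prof = protein_fraction_ratios(quants, cfg.calibration)
            totals.extend(prof.total_ratio[p] for p in ("MIC10", "MIC26", "MIC27"))
        totals = np.array(totals)
        se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - 0.3) <= 3 * se

    def test_determinism(self):
        a, _ = simulate_complexome(micos_knockdown_config(seed=5))
        b, _ = simulate_complexome(micos_knockdown_config(seed=5))
        assert a == b

    def test_mass_outside_range_rejected(self):
        cfg = ComplexomeSimConfig(complexes=[ComplexSpec(2000.0, ("A",))], seed=0)
        with pytest.raises(ValueError, match="outside calibration"):
            simulate_complexome(cfg)


class TestSimulateMicrograph:
    def test_zero_particles(self):
        cfg = GoldSimConfig(cristae_paths=SEG, cj_points=[[0.0, 0.0]],
                            n_particles=0, seed=0)
        ann, truth = simulate_micrograph(cfg)
        assert len(ann.particles) == 0

    def test_cj_concentrated_matches_halfnormal_cdf(self):
        """With sigma = 30 nm, the expected fraction within 50 nm of the CJ is
        the half-normal CDF erf(50 / (30 sqrt(2))) ~ 0.904."""
        cfg = GoldSimConfig(cristae_paths=SEG, cj_points=[[2000.0, 0.0]],
                            n_particles=1000, placement="cj_concentrated",
                            sigma_nm=30.0, seed=2)
        ann, truth = simulate_micrograph(cfg)
        frac = float(np.mean(nearest_cj_distance(ann) < 50.0))
        expected = erf(50.0 / (30.0 * math.sqrt(2)))
        assert abs(frac - expected) <= 0.05
        assert len(truth["arc_displacement"]) == 1000

    def test_uniform_on_segment_mean_distance(self):
        cfg = GoldSimConfig(cristae_paths=[np.array([[0.0, 0.0], [1000.0, 0.0]])],
                            cj_points=[[0.0, 0.0]], n_particles=2000,
                            placement="uniform", seed=4)
        ann, _ = simulate_micrograph(cfg)
        assert nearest_cj_distance(ann).mean() == pytest.approx(500.0, abs=40.0)

    def test_determinism(self):
        cfg = GoldSimConfig(cristae_paths=SEG, cj_points=[[100.0, 0.0]],
                            n_particles=50, placement="cj_concentrated", seed=9)
        a, _ = simulate_micrograph(cfg)
        b, _ = simulate_micrograph(cfg)
        assert np.array_equal(a.particles, b.particles)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            simulate_micrograph(GoldSimConfig(cristae_paths=[], cj_points=[[0.0, 0.0]],
                                              n_particles=5, seed=0))

    def test_unknown_placement_rejected(self):
        with pytest.raises(ValueError, match="placement"):
            GoldSimConfig(cristae_paths=SEG, cj_points=[[0.0, 0.0]], placement="ring")
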