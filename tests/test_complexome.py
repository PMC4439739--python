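import math

import numpy as np
import pytest

from micoskit.complexome import (
    FractionCalibration,
    PeptideQuant,
    calibrate_fractions,
    detect_shift,
    mass_to_slice,
    protein_fraction_ratios,
    read_peptide_quants,
    render_heatmap,
    total_abundance_ratios,
    write_peptide_quants,
)


def quant(pep, prot, frac, heavy, light):
    return PeptideQuant(peptide=pep, protein=prot, fraction=frac,
                        heavy_intensity=heavy, light_intensity=light)


class TestCalibration:
    def test_top_mass_is_slice_one(self):
        assert mass_to_slice(calibrate_fractions(), 1000.0) == 1

    def test_700_kda_falls_in_slice_three(self):
        # (log10 1000 - log10 700) / ((log10 1000 - log10 60)/20) = 2.54
        assert mass_to_slice(calibrate_fractions(), 700.0) == 3

    def test_below_range_clamps_to_last_slice(self):
        idx, clamped = mass_to_slice(calibrate_fractions(), 10.0, return_clamp=True)
        assert (idx, clamped) == (20, True)

    def test_above_range_clamps_to_first_slice(self):
        idx, clamped = mass_to_slice(calibrate_fractions(), 2000.0, return_clamp=True)
        assert (idx, clamped) == (1, True)

    def test_edges_strictly_decreasing(self):
        edges = calibrate_fractions(20, 1000, 60).log_edges
        assert len(edges) == 21
        assert (np.diff(edges) < 0).all()

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mass_to_slice(calibrate_fractions(), 0.0)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            FractionCalibration(mass_top=60.0, mass_bottom=1000.0)


class TestFractionRatios:
    def test_one_to_one_mixing(self):
        quants = [quant("p1", "A", f, 100.0, 100.0) for f in (1, 5, 9)]
        prof = protein_fraction_ratios(quants)
        assert prof.ratios.loc["A", [1, 5, 9]].tolist() == [1.0, 1.0, 1.0]
        assert prof.total_ratio["A"] == 1.0

    def test_summed_intensity_quotient(self):
        quants = [quant("p1", "A", 3, 100.0, 50.0), quant("p2", "A", 3, 300.0, 150.0)]
        prof = protein_fraction_ratios(quants)
        assert prof.ratios.loc["A", 3] == pytest.approx(2.0)  # 400/200

    def test_light_absent_caps_and_flags(self):
        prof = protein_fraction_ratios([quant("p1", "A", 2, 500.0, 0.0)], cap=100.0)
        assert prof.ratios.loc["A", 2] == 100.0
        assert bool(prof.capped.loc["A", 2])

    def test_heavy_absent_gives_zero(self):
        prof = protein_fraction_ratios([quant("p1", "A", 2, 0.0, 500.0)])
        assert prof.ratios.loc["A", 2] == 0.0

    def test_unquantified_fraction_is_missing(self):
        prof = protein_fraction_ratios([quant("p1", "A", 2, 10.0, 10.0)])
        assert math.isnan(prof.ratios.loc["A", 10])

    def test_fraction_outside_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration range"):
            protein_fraction_ratios([quant("p1", "A", 25, 1.0, 1.0)])

    def test_channel_scaling_invariance(self, rng):
        quants = [
            quant(f"p{i}", "A", int(rng.integers(1, 21)),
                  float(rng.uniform(10, 100)), float(rng.uniform(10, 100)))
            for i in range(12)
        ]
        scaled = [
            quant(q.peptide, q.protein, q.fraction,
                  q.heavy_intensity * 7.5, q.light_intensity * 7.5)
            for q in quants
        ]
        a = protein_fraction_ratios(quants)
        b = protein_fraction_ratios(scaled)
        assert np.allclose(a.ratios.to_numpy(), b.ratios.to_numpy(), equal_nan=True)

    def test_protein_ratio_between_peptide_extremes(self, rng):
        quants = [
            quant(f"p{i}", "A", 4, float(rng.uniform(10, 200)), float(rng.uniform(10, 200)))
            for i in range(6)
        ]
        prof = protein_fraction_ratios(quants)
        pep_ratios = [q.heavy_intensity / q.light_intensity for q in quants]
        assert min(pep_ratios) <= prof.ratios.loc["A", 4] <= max(pep_ratios)

    def test_median_method(self):
        quants = [quant("p1", "A", 1, 10.0, 10.0), quant("p2", "A", 1, 90.0, 30.0)]
        prof = protein_fraction_ratios(quants, method="median")
        assert prof.ratios.loc["A", 1] == pytest.approx(2.0)  # median of {1, 3}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            protein_fraction_ratios([])


class TestTotalAbundanceRatios:
    def test_summed_over_fractions(self):
        quants = [quant("p1", "A", f, h, l)
                  for f, h, l in [(1, 10, 30), (2, 20, 40), (3, 30, 50)]]
        pep, prot = total_abundance_ratios(quants)
        assert pep.loc[pep.peptide == "p1", "ratio"].item() == pytest.approx(0.5)
        assert prot["A"] == pytest.approx(0.5)

    def test_equal_channels_give_one(self):
        pep, prot = total_abundance_ratios([quant("p1", "A", 1, 7.0, 7.0)])
        assert prot["A"] == 1.0

    def test_light_only_peptide_is_zero(self):
        pep, _ = total_abundance_ratios([quant("p1", "A", 1, 0.0, 9.0)])
        assert pep["ratio"].item() == 0.0

    def test_total_equals_intensity_weighted_recombination(self, rng):
        quants = [
            quant(f"p{i}", "A", int(rng.integers(1, 6)),
                  float(rng.uniform(5, 50)), float(rng.uniform(5, 50)))
            for i in range(15)
        ]
        prof = protein_fraction_ratios(quants)
        _, prot = total_abundance_ratios(quants)
        light = np.zeros(21)
        heavy = np.zeros(21)
        for q in quants:
            light[q.fraction] += q.light_intensity
            heavy[q.fraction] += q.heavy_intensity
        recombined = sum(
            prof.ratios.loc["A", f] * light[f] for f in range(1, 21) if light[f] > 0
        ) / light.sum()
        assert prot["A"] == pytest.approx(recombined)
        assert prot["A"] == pytest.approx(heavy.sum() / light.sum())


def flat_profile(value=1.0, proteins=("A",), slices=range(1, 21)):
    quants = [quant(f"{p}_x", p, f, value * 10.0, 10.0) for p in proteins for f in slices]
    return protein_fraction_ratios(quants)


class TestDetectShift:
    def test_flat_unity_profile_is_no_change(self):
        calls = detect_shift(flat_profile(1.0))
        assert calls[0].call == "no_change"

    def test_windowed_shift_pattern(self):
        # -1 in the 700 kDa window (slices 2-4), +1 at the 500 kDa window (5-6)
        quants = []
        for f in range(1, 21):
            ratio = 0.5 if f in (2, 3, 4) else 2.0 if f in (5, 6) else 1.0
            quants.append(quant("p1", "A", f, ratio * 10.0, 10.0))
        calls = detect_shift(protein_fraction_ratios(quants))
        assert calls[0].call == "subcomplex_shift"
        assert calls[0].mature_log2 == pytest.approx(-1.0)
        assert calls[0].sub_log2 == pytest.approx(1.0)

    def test_global_loss_without_accumulation_is_degraded(self):
        calls = detect_shift(flat_profile(0.3))
        assert calls[0].call == "degraded"
        assert calls[0].total_log2 == pytest.approx(math.log2(0.3))

    def test_mature_loss_with_stable_total_is_depleted(self):
        # loss only at the mature window; elsewhere 1.2 keeps the total high
        quants = []
        for f in range(1, 21):
            ratio = 0.5 if f in (2, 3, 4) else 1.2
            quants.append(quant("p1", "A", f, ratio * 10.0, 10.0))
        calls = detect_shift(protein_fraction_ratios(quants))
        assert calls[0].call == "depleted"

    def test_empty_window_flags_insufficient_data(self):
        prof = flat_profile(1.0, slices=[1, 10, 15])  # nothing near 700 kDa
        calls = detect_shift(prof)
        assert calls[0].call == "insufficient_data"

    def test_overlapping_windows_are_disjoint(self):
        # slice 4 belongs to both +/-1 windows; it must count toward mature only,
        # so a depressed slice 4 cannot mask accumulation at slices 5-6
        quants = []
        for f in range(1, 21):
            ratio = 0.5 if f in (2, 3, 4) else 2.0 if f in (5, 6) else 1.0
            quants.append(quant("p1", "A", f, ratio * 10.0, 10.0))
        calls = detect_shift(protein_fraction_ratios(quants))
        assert calls[0].sub_log2 == pytest.approx(1.0)


class TestHeatmapAndIO:
    def test_heatmap_file_written(self, tmp_path):
        prof = flat_profile(proteins=("A", "B"))
        out = tmp_path / "heatmap.png"
        render_heatmap(prof, out)
        assert out.stat().st_size > 0

    def test_quant_round_trip(self, tmp_path):
        quants = [quant("p1", "A", 3, 12.5, 8.0), quant("p2", "B", 7, 0.0, 4.0)]
        path = tmp_path / "quants.tsv"
        write_peptide_quants(quants, path)
        assert read_peptide_quants(path) == quants

    def test_column_mapping(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text("Sequence\tProteins\tFraction\tIntensity H\tIntensity L\n"
                        "PEPTIDEA\tA\t3\t100\t50\n")
        quants = read_peptide_quants(path, columns={
            "peptide": "Sequence", "protein": "Proteins", "fraction": "Fraction",
            "heavy_intensity": "Intensity H", "light_intensity": "Intensity L",
        })
        assert quants[0].heavy_intensity == 100.0

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peptide\tprotein\tfraction\theavy_intensity\np\tA\t1\t5\n")
        with pytest.raises(ValueError, match="light_intensity"):
            read_peptide_quants(path)
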