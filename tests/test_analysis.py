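"""Fragmentomics statistics: classification, dedup, modality/periodicity, profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cffrag import (
    CLASSES,
    LengthHistogram,
    PopulationConfig,
    SizeClassConfig,
    annotate_fragments,
    bin_coverage,
    chrom_distribution,
    deduplicate,
    element_profile,
    library_to_insert,
    modal_length,
    pearson_matrix,
    periodicity,
    quantify_trace,
    simulate_population,
    size_binned_profile,
    size_filter_classify,
    synthesize_trace,
)
from cffrag.analysis import default_size_bins
from cffrag.fixtures import ElementAnnotation, GenomeModel
from cffrag.fragments import SchemaError

from conftest import fragments_of_lengths, make_fragments


class TestSizeClassification:
    def test_boundary_lengths(self):
        fr = fragments_of_lengths([24, 25, 50, 100, 101, 250, 251])
        parts = size_filter_classify(fr)
        assert sorted(parts["uscf"]["length"]) == [25, 50, 100]
        assert sorted(parts["mncf"]["length"]) == [101, 250]
        assert sorted(parts["excluded"]["length"]) == [24, 251]

    def test_enumeration_of_every_length_1_to_300(self):
        fr = fragments_of_lengths(range(1, 301))
        parts = size_filter_classify(fr)
        assert len(parts["uscf"]) == 76
        assert len(parts["mncf"]) == 150
        assert len(parts["excluded"]) == 74

    def test_empty_input_gives_three_empty_sets(self):
        fr = fragments_of_lengths([])
        parts = size_filter_classify(fr)
        assert all(len(v) == 0 for v in parts.values())

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=400), max_size=60))
    def test_partition_is_exhaustive_and_disjoint(self, lengths):
        fr = fragments_of_lengths(lengths)
        parts = size_filter_classify(fr)
        assert sum(len(v) for v in parts.values()) == len(fr)
        all_lengths = np.concatenate(
            [v["length"].to_numpy() for v in parts.values()]
        ) if len(fr) else np.array([])
        assert sorted(all_lengths) == sorted(lengths)

    def test_misordered_ranges_rejected(self):
        with pytest.raises(ValueError):
            SizeClassConfig(uscf_range=(25, 120), mncf_range=(101, 250))


class TestDeduplicate:
    def test_same_coordinates_same_umi_collapse(self):
        fr = fragments_of_lengths([50, 50])
        fr.loc[:, ["start", "end", "umi"]] = [[100, 150, "AAAA"], [100, 150, "AAAA"]]
        fr["length"] = fr["end"] - fr["start"]
        assert len(deduplicate(fr)) == 1

    def test_same_coordinates_different_umi_survive(self):
        fr = fragments_of_lengths([50, 50])
        fr.loc[:, "start"] = 100
        fr.loc[:, "end"] = 150
        fr["length"] = 50
        fr["umi"] = ["AAAA", "CCCC"]
        assert len(deduplicate(fr)) == 2

    def test_planted_duplicates_match_key_set_oracle(self):
        rng = np.random.default_rng(0)
        n = 10_000
        base = pd.DataFrame(
            {
                "contig": rng.choice(["chrA", "chrB"], n),
                "start": rng.integers(0, 5_000, n),
                "strand": rng.choice(["+", "-"], n),
                "umi": rng.choice([f"U{i}" for i in range(64)], n),
            }
        )
        base["end"] = base["start"] + rng.integers(25, 250, n)
        # plant exact duplicates for ~20% of rows
        dup = base.sample(frac=0.2, random_state=1)
        df = pd.concat([base, dup], ignore_index=True)
        df["length"] = df["end"] - df["start"]
        df["duplex_length"] = df["length"]
        df["state"] = "ss"
        df["nicks"] = ""
        df["population"] = "uscf"
        df["treatment_history"] = ""
        expected = len({t for t in df[["contig", "start", "end", "strand", "umi"]].itertuples(index=False)})
        assert len(deduplicate(df)) == expected

    def test_missing_umi_is_an_error(self):
        fr = fragments_of_lengths([50])
        fr["umi"] = ""
        with pytest.raises(SchemaError, match="UMI"):
            deduplicate(fr)


class TestModalLength:
    def test_argmax(self):
        assert modal_length(LengthHistogram.from_counts({49: 3, 50: 10, 51: 2})) == 50

    def test_tie_breaks_toward_smaller_length(self):
        assert modal_length(LengthHistogram.from_counts({50: 5, 60: 5})) == 50

    def test_empty_histogram_is_an_error(self):
        hist = LengthHistogram(lengths=np.array([50]), counts=np.array([0]))
        with pytest.raises(ValueError):
            modal_length(hist)


class TestPeriodicity:
    @pytest.mark.parametrize("spacing", [10, 7])
    def test_synthetic_comb_recovers_spacing(self, spacing):
        counts = {}
        for L in range(95, 166):
            counts[L] = 10 + (100 if (L - 100) % spacing == 0 else 0)
        result = periodicity(LengthHistogram.from_counts(counts), window=(100, 160))
        assert result.period == spacing
        assert result.contrast > 0.5

    def test_window_shorter_than_twice_max_period_rejected(self):
        hist = LengthHistogram.from_counts({L: 5 for L in range(100, 161)})
        with pytest.raises(ValueError, match="twice"):
            periodicity(hist, window=(100, 130), periods=range(2, 21))

    def test_default_simulation_ladder_has_period_10(self, default_sim):
        hist = LengthHistogram.from_fragments(size_filter_classify(default_sim)["mncf"])
        assert periodicity(hist).period == 10


class TestChromDistribution:
    def test_single_contig_fraction_is_one(self):
        g = GenomeModel((("chrA", 100_000), ("chrM", 1_000)))
        fr = fragments_of_lengths([50] * 10)
        dist = chrom_distribution(fr, g)
        assert dist.loc["chrA", "fraction"] == 1.0
        assert dist["fraction"].sum() == pytest.approx(1.0)

    def test_unknown_contig_is_an_error(self, toy_genome):
        fr = fragments_of_lengths([50], contig="chrZ")
        with pytest.raises(ValueError, match="chrZ"):
            chrom_distribution(fr, toy_genome)

    def test_uniform_placement_equalizes_per_mb_density(self, default_genome, uniform_sim):
        dist = chrom_distribution(uniform_sim, default_genome)
        pA, pB = dist.loc["chrA", "fraction"], dist.loc["chrB", "fraction"]
        n = len(uniform_sim)
        se = math.sqrt(0.5 * 0.5 / n)
        assert abs(pA - pB) <= 3 * 2 * se

    def test_default_sim_chrm_fraction_below_point1_pct(self, default_genome, uniform_sim):
        dist = chrom_distribution(uniform_sim, default_genome)
        assert dist.loc["chrM", "fraction"] <= 0.001


class TestBinnedCoverage:
    def test_first_bin_assignment(self, toy_genome):
        fr = make_fragments([{"contig": "chr1", "start": 0, "end": 50}])
        cov = bin_coverage(fr, toy_genome, bin_size=100)
        assert cov.vector[0] == 1

    def test_midpoint_on_boundary_goes_to_right_bin(self, toy_genome):
        # [50, 150) has midpoint 100, which belongs to bin 1 under half-open bins
        fr = make_fragments([{"contig": "chr1", "start": 50, "end": 150}])
        cov = bin_coverage(fr, toy_genome, bin_size=100)
        assert cov.vector[0] == 0 and cov.vector[1] == 1

    def test_vector_length_and_conservation(self, toy_genome, toy_annotation):
        fr = simulate_population(
            toy_genome, toy_annotation, PopulationConfig(n_total=5_000), seed=2
        )
        cov = bin_coverage(fr, toy_genome, bin_size=100)
        expected_bins = sum(-(-l // 100) for _, l in toy_genome.contigs)
        assert len(cov.vector) == expected_bins
        assert cov.total == len(fr)


class TestPearson:
    def test_self_correlation_is_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        mat = pearson_matrix([v, v.copy()])
        assert mat.iloc[0, 1] == pytest.approx(1.0)

    def test_negation_about_mean_is_minus_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = 2 * v.mean() - v
        assert pearson_matrix([v, w]).iloc[0, 1] == pytest.approx(-1.0)

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        vs = [rng.poisson(5, 200).astype(float) for _ in range(4)]
        mat = pearson_matrix(vs).to_numpy()
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)

    def test_zero_variance_vector_names_the_sample(self):
        with pytest.raises(ValueError, match="flat"):
            pearson_matrix([np.array([1.0, 2.0]), np.ones(2)], names=["ok", "flat"])

    def test_replicate_coverages_correlate_above_shuffled(self, toy_genome, toy_annotation):
        cfg = PopulationConfig(n_total=20_000)
        rng = np.random.default_rng(0)
        for seed in range(10):
            a = simulate_population(toy_genome, toy_annotation, cfg, seed=100 + seed)
            b = simulate_population(toy_genome, toy_annotation, cfg, seed=200 + seed)
            va = bin_coverage(a, toy_genome).vector.astype(float)
            vb = bin_coverage(b, toy_genome).vector.astype(float)
            shuffled = rng.permutation(vb)
            r_ab = pearson_matrix([va, vb]).iloc[0, 1]
            r_shuf = pearson_matrix([va, shuffled]).iloc[0, 1]
            assert r_ab > r_shuf


class TestElementProfiles:
    def test_midpoint_class_matches_per_bp_oracle(self, toy_genome, toy_annotation):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(300):
            contig, clen = toy_genome.contigs[rng.integers(0, 2)]
            L = int(rng.integers(25, 200))
            start = int(rng.integers(0, clen - L))
            rows.append({"contig": contig, "start": start, "end": start + L})
        fr = make_fragments(rows)
        got = annotate_fragments(fr, toy_annotation)
        feats = toy_annotation.raw_features
        for i, row in fr.iterrows():
            mid = (row["start"] + row["end"]) // 2
            sub = feats[(feats["contig"] == row["contig"]) & (feats["start"] <= mid) & (mid < feats["end"])]
            expected = (
                CLASSES[min(CLASSES.index(k) for k in sub["klass"])] if len(sub) else "intergenic"
            )
            assert got[i] == expected

    def test_overlapping_promoter_wins_over_exon(self):
        g = GenomeModel((("chr1", 10_000), ("chrM", 1_000)))
        feats = pd.DataFrame(
            [("chr1", 2_000, 4_000, "exon", "+"), ("chr1", 3_000, 5_000, "promoter", "+")],
            columns=["contig", "start", "end", "klass", "strand"],
        )
        ann = ElementAnnotation.from_features(g, feats)
        fr = make_fragments([{"contig": "chr1", "start": 3_400, "end": 3_500}])
        assert annotate_fragments(fr, ann)[0] == "promoter"  # midpoint 3450

    def test_midpoint_outside_genome_is_an_error(self, toy_annotation):
        fr = make_fragments([{"contig": "chrM", "start": 4_990, "end": 5_010}])
        with pytest.raises(ValueError):
            annotate_fragments(fr, toy_annotation)

    def test_all_exonic_fragments_give_unit_exon_proportion(self, toy_annotation):
        classes = pd.Series(["exon"] * 10)
        prof = element_profile(classes, toy_annotation.baseline)
        assert prof.proportions["exon"] == 1.0
        assert sum(prof.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_fragments_is_an_error(self, toy_annotation):
        with pytest.raises(ValueError):
            element_profile(pd.Series(dtype=object), toy_annotation.baseline)

    def test_enriched_directions_match_between_populations(
        self, default_annotation, default_sim
    ):
        baseline = default_annotation.baseline
        for pop, promoter_side in (("uscf", "up"), ("mncf", "down")):
            sub = default_sim[default_sim["population"] == pop]
            prof = element_profile(annotate_fragments(sub, default_annotation), baseline)
            if promoter_side == "up":
                assert prof.ratio_to_baseline["promoter"] > 1
                assert prof.ratio_to_baseline["intergenic"] < 1
            else:
                assert prof.ratio_to_baseline["promoter"] < 1
                assert prof.ratio_to_baseline["intergenic"] > 1


class TestSizeBinnedProfile:
    def test_single_length_fills_only_its_bin(self, toy_annotation):
        fr = fragments_of_lengths([47] * 20, contig="chr1")
        prof = size_binned_profile(fr, toy_annotation)
        bin_47 = prof[(prof["bin_lo"] == 45) & (prof["class"] == "intergenic")]
        assert bin_47["n"].iloc[0] == 20
        other = prof[(prof["bin_lo"] != 45)]
        assert other["proportion"].isna().all()

    def test_bins_tile_25_to_100_with_final_bin_closed(self):
        bins = default_size_bins()
        assert bins[0] == (25, 35)
        assert bins[-1] == (95, 101)
        assert len(bins) == 8

    def test_uniform_placement_ratios_near_one_per_bin(
        self, default_annotation, uniform_sim
    ):
        parts = size_filter_classify(uniform_sim)
        prof = size_binned_profile(parts["uscf"], default_annotation)
        baseline = default_annotation.baseline
        for _, row in prof.dropna(subset=["ratio"]).iterrows():
            b = baseline[row["class"]]
            se = math.sqrt(b * (1 - b) / row["n"])
            assert abs(row["proportion"] - b) <= 4 * se, (row["bin_lo"], row["class"])

    def test_promoter_peaks_at_45_55_and_intergenic_rises_toward_100(
        self, default_annotation, default_sim
    ):
        parts = size_filter_classify(default_sim)
        prof = size_binned_profile(parts["uscf"], default_annotation)
        promoter = prof[prof["class"] == "promoter"].set_index("bin_lo")["ratio"]
        assert promoter.idxmax() == 45
        intergenic = prof[prof["class"] == "intergenic"].set_index("bin_lo")["ratio"]
        assert intergenic[95] > intergenic[55]


class TestTraceQuantification:
    def test_all_intensity_in_region_a(self):
        lib = pd.DataFrame({"library_size": [200] * 100})
        assert quantify_trace(synthesize_trace(lib, kernel_sigma=2.0)) == pytest.approx(1.0, abs=1e-6)

    def test_equal_areas_give_half(self):
        lib = pd.DataFrame({"library_size": [200] * 400 + [300] * 400})
        assert quantify_trace(synthesize_trace(lib, kernel_sigma=2.0)) == pytest.approx(0.5, abs=0.005)

    def test_count_ratio_oracle_30_70(self):
        lib = pd.DataFrame({"library_size": [200] * 300 + [300] * 700})
        assert quantify_trace(synthesize_trace(lib, kernel_sigma=2.0)) == pytest.approx(0.30, abs=0.01)

    def test_alternate_region_b_variant(self):
        lib = pd.DataFrame({"library_size": [200] * 300 + [300] * 700})
        tr = synthesize_trace(lib, kernel_sigma=2.0)
        got = quantify_trace(tr, region_b=(250, 350))
        assert got == pytest.approx(0.30, abs=0.01)

    def test_region_outside_axis_is_an_error(self):
        lib = pd.DataFrame({"library_size": [200] * 10})
        tr = synthesize_trace(lib)
        with pytest.raises(ValueError, match="axis"):
            quantify_trace(tr, region_a=(10, 250))

    def test_zero_intensity_in_regions_is_an_error(self):
        lib = pd.DataFrame({"library_size": [600] * 10})
        tr = synthesize_trace(lib, kernel_sigma=1.0)
        with pytest.raises(ValueError, match="zero"):
            quantify_trace(tr)


class TestLibraryToInsert:
    @pytest.mark.parametrize("library,insert", [(200, 50), (300, 150)])
    def test_adapter_subtraction(self, library, insert):
        assert library_to_insert(library) == insert

    def test_adapter_dimer_regime_is_an_error(self):
        with pytest.raises(ValueError, match="adapter"):
            library_to_insert(150)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=151, max_value=2_000))
    def test_inverse_of_adapter_addition(self, library):
        assert library_to_insert(library) + 150 == library
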