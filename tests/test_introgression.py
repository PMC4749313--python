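"""Derived allele frequencies, ΔDAF scan, aiSNP regions, wolf-allele ranking."""

import numpy as np
import pandas as pd
import pytest

from conftest import write_vcf
from dogcnv.errors import InputError, ValidationError
from dogcnv.introgression import (Locus, aisnps_in_region, chromosome_control,
                                  delta_daf_scan, derived_allele_freq,
                                  gene_region, load_dosage_table,
                                  load_genotypes_vcf, load_population_map,
                                  threshold_moments, wolf_allele_freq_by_breed)
from dogcnv.io import GeneRegion
from dogcnv.simulate import GenoSimConfig, simulate_genotypes


def _loci(n, chrom="chr1", spacing=1000):
    return [Locus(chrom, (i + 1) * spacing, "A", "G") for i in range(n)]


def _freq_df(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({"daf": values,
                         "n_chrom": np.where(np.isnan(values), 0, 10)})


class TestDerivedAlleleFreq:
    def test_direct_dosage_count(self):
        dos = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [2.0]})
        out = derived_allele_freq(dos, ["a", "b", "c"])
        assert out["daf"].iloc[0] == pytest.approx(0.5)
        assert out["n_chrom"].iloc[0] == 6

    def test_all_missing_locus_flagged(self):
        dos = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
        out = derived_allele_freq(dos, ["a", "b"])
        assert np.isnan(out["daf"].iloc[0])
        assert out["n_chrom"].iloc[0] == 0

    def test_matches_naive_recount_on_random_matrix(self):
        rng = np.random.default_rng(42)
        mat = rng.integers(0, 3, (100, 50)).astype(float)
        mat[rng.random((100, 50)) < 0.1] = np.nan
        dos = pd.DataFrame(mat, columns=[f"s{i}" for i in range(50)])
        out = derived_allele_freq(dos, list(dos.columns))
        for i in range(100):
            row = mat[i]
            obs = row[~np.isnan(row)]
            if obs.size:
                assert out["daf"].iloc[i] == pytest.approx(obs.sum() / (2 * obs.size))
            else:
                assert np.isnan(out["daf"].iloc[i])

    def test_unknown_sample_rejected(self):
        dos = pd.DataFrame({"a": [0.0]})
        with pytest.raises(ValidationError, match="ghost"):
            derived_allele_freq(dos, ["ghost"])


class TestDeltaDafScan:
    def test_identical_panels_degenerate(self):
        f = _freq_df([0.1, 0.5, 0.9])
        scan, summary = delta_daf_scan(f, f)
        assert np.all(scan["delta_daf"] == 0.0)
        assert summary.degenerate
        assert summary.n_flagged == 0

    def test_symmetric_three_point_set(self):
        scan, summary = delta_daf_scan(_freq_df([0.3, 0.5, 0.7]),
                                       _freq_df([0.5, 0.5, 0.5]))
        assert summary.genome_mean == pytest.approx(0.0)
        assert summary.genome_sd == pytest.approx(0.2)
        assert summary.upper_threshold == pytest.approx(0.4)
        assert summary.lower_threshold == pytest.approx(-0.4)
        assert summary.n_flagged == 0

    def test_delta_bounds_and_exactness(self, geno_bundle):
        _, _, dosages, pop_map, _ = geno_bundle
        dogs = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                             if p != "wolf"])
        wolves = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                               if p == "wolf"])
        scan, _ = delta_daf_scan(dogs, wolves)
        delta = scan["delta_daf"]
        assert ((delta >= -1) & (delta <= 1)).all()
        assert np.allclose(delta, scan["daf_dogs"] - scan["daf_wolves"])

    def test_swapping_panels_negates_everything(self):
        a = _freq_df([0.1, 0.4, 0.9, 0.2])
        b = _freq_df([0.3, 0.2, 0.1, 0.8])
        scan_ab, sum_ab = delta_daf_scan(a, b)
        scan_ba, sum_ba = delta_daf_scan(b, a)
        assert np.allclose(scan_ba["delta_daf"], -scan_ab["delta_daf"])
        assert sum_ba.genome_mean == pytest.approx(-sum_ab.genome_mean)
        assert sum_ba.upper_threshold == pytest.approx(-sum_ab.lower_threshold)

    def test_raising_multiplier_never_adds_flags(self):
        rng = np.random.default_rng(0)
        a = _freq_df(rng.random(200))
        b = _freq_df(rng.random(200))
        _, two = delta_daf_scan(a, b, multiplier=2.0)
        _, three = delta_daf_scan(a, b, multiplier=3.0)
        assert not np.any(three.flags & ~two.flags)

    def test_locus_order_permutation_invariant_moments(self):
        rng = np.random.default_rng(1)
        av, bv = rng.random(50), rng.random(50)
        perm = rng.permutation(50)
        _, base = delta_daf_scan(_freq_df(av), _freq_df(bv))
        _, permuted = delta_daf_scan(_freq_df(av[perm]), _freq_df(bv[perm]))
        assert permuted.genome_mean == pytest.approx(base.genome_mean)
        assert permuted.genome_sd == pytest.approx(base.genome_sd)

    def test_too_few_loci_rejected(self):
        with pytest.raises(InputError):
            delta_daf_scan(_freq_df([0.1]), _freq_df([0.2]))


class TestThresholdMoments:
    def test_builder_inverts_on_any_scan(self):
        rng = np.random.default_rng(2)
        _, summary = delta_daf_scan(_freq_df(rng.random(100)),
                                    _freq_df(rng.random(100)))
        mean, sd = threshold_moments(summary.upper_threshold,
                                     summary.lower_threshold)
        assert mean == pytest.approx(summary.genome_mean, abs=1e-15)
        assert sd == pytest.approx(summary.genome_sd, abs=1e-15)

    def test_inverted_order_rejected(self):
        with pytest.raises(InputError):
            threshold_moments(-0.5, 0.5)


class TestChromosomeControl:
    def test_whole_genome_self_comparison(self):
        loci = _loci(20, "chr6")
        scan = pd.DataFrame({"delta_daf": np.linspace(-0.5, 0.5, 20)})
        res = chromosome_control(scan, loci, "chr6")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_unknown_chromosome_rejected(self):
        loci = _loci(5)
        scan = pd.DataFrame({"delta_daf": np.zeros(5)})
        with pytest.raises(InputError):
            chromosome_control(scan, loci, "chrX")

    def test_shifted_chromosome_detected(self):
        rng = np.random.default_rng(3)
        loci = _loci(400, "chr1") + _loci(100, "chr6")
        delta = np.concatenate([rng.normal(0, 0.2, 400),
                                rng.normal(0.3, 0.2, 100)])
        res = chromosome_control(pd.DataFrame({"delta_daf": delta}), loci, "chr6")
        assert res.p_value < 0.05

    def test_null_chromosome_rejection_calibrated(self):
        """A chromosome drawn from the same generator rejects at ~5%."""
        rng = np.random.default_rng(4)
        loci = _loci(400, "chr1") + _loci(100, "chr6")
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            delta = rng.normal(0, 0.2, 500)
            if chromosome_control(pd.DataFrame({"delta_daf": delta}), loci,
                                  "chr6").p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.09


class TestGeneRegion:
    def test_tss_window_arithmetic(self):
        region = gene_region("AMY2B", "chr6", 1_000_000, 2_000_000, pad=500_000)
        assert (region.window_start, region.window_end) == (500_000, 2_500_000)

    def test_start_clamped_at_zero(self):
        region = gene_region("X", "chr1", 200_000, 1_000_000, pad=500_000)
        assert region.window_start == 0

    def test_zero_pad_spans_exactly_the_tss_interval(self):
        region = gene_region("X", "chr1", 100, 900, pad=0)
        assert (region.window_start, region.window_end) == (100, 900)

    def test_inverted_tss_rejected(self):
        with pytest.raises(InputError):
            gene_region("X", "chr1", 900, 100)


class TestAisnpsInRegion:
    def _scan(self, flags):
        return pd.DataFrame({"delta_daf": np.zeros(len(flags)), "aisnp": flags})

    def test_empty_when_no_flags_inside(self):
        loci = _loci(5, "chr1")
        region = GeneRegion("X", "chr2", 0, 10_000)
        assert aisnps_in_region(self._scan([True] * 5), loci, region) == []

    def test_planted_inside_vs_outside(self):
        config = GenoSimConfig(seed=9, n_planted_outside=5)
        loci, dosages, pop_map, truth = simulate_genotypes(config)
        dogs = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                             if p != "wolf"])
        wolves = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                               if p == "wolf"])
        scan, _ = delta_daf_scan(dogs, wolves)
        inside = aisnps_in_region(scan, loci, config.planted_region)
        assert set(truth["planted_in_region"]).issubset(inside)
        assert not set(truth["planted_outside"]) & set(inside)

    def test_window_end_excluded_half_open(self):
        loci = [Locus("chr1", 999, "A", "G"), Locus("chr1", 1000, "A", "G")]
        region = GeneRegion("X", "chr1", 0, 1000)
        assert aisnps_in_region(self._scan([True, True]), loci, region) == [0]


class TestWolfAlleleFreq:
    def test_breed_fixed_for_wolf_allele(self):
        # wolves fixed derived; breed fixed derived -> frequency 1.0
        dos = pd.DataFrame({"d0": [2.0], "d1": [2.0], "w0": [2.0], "w1": [2.0]})
        pop_map = {"d0": "b", "d1": "b", "w0": "wolf", "w1": "wolf"}
        wolves = derived_allele_freq(dos, ["w0", "w1"])
        loci = _loci(1)
        freqs, ranking = wolf_allele_freq_by_breed(dos, pop_map, wolves, loci, [0])
        assert freqs[0].wolf_allele == "G"
        assert freqs[0].wolf_allele_freq == 1.0
        assert ranking == ["b"]

    def test_wolf_frequency_tie_flagged_and_derived_chosen(self):
        dos = pd.DataFrame({"d0": [0.0], "w0": [1.0]})  # wolves het: DAF 0.5
        pop_map = {"d0": "b", "w0": "wolf"}
        wolves = derived_allele_freq(dos, ["w0"])
        freqs, _ = wolf_allele_freq_by_breed(dos, pop_map, wolves, _loci(1), [0])
        assert freqs[0].tie_flag
        assert freqs[0].wolf_allele == "G"

    def test_missing_breed_rejected(self, geno_bundle):
        _, loci, dosages, pop_map, _ = geno_bundle
        wolves = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                               if p == "wolf"])
        with pytest.raises(ValidationError, match="nothere"):
            wolf_allele_freq_by_breed(dosages, pop_map, wolves, loci, [0],
                                      breeds=["nothere"])

    def test_introgressed_breed_ranks_first(self, geno_bundle):
        config, loci, dosages, pop_map, truth = geno_bundle
        dogs = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                             if p != "wolf"])
        wolves = derived_allele_freq(dosages, [s for s, p in pop_map.items()
                                               if p == "wolf"])
        scan, _ = delta_daf_scan(dogs, wolves)
        idx = aisnps_in_region(scan, loci, config.planted_region)
        _, ranking = wolf_allele_freq_by_breed(dosages, pop_map, wolves, loci, idx)
        assert ranking[0] == truth["introgressed_breed"]


class TestGenotypeIO:
    def test_vcf_roundtrip_matches_dosage_matrix(self, tmp_path, geno_bundle):
        _, loci, dosages, pop_map, _ = geno_bundle
        sub_idx = list(range(40))
        sub_loci = [loci[i] for i in sub_idx]
        sub = dosages.iloc[sub_idx].reset_index(drop=True)
        vcf_path = tmp_path / "panel.vcf"
        write_vcf(vcf_path, sub_loci, sub)
        loaded_loci, loaded = load_genotypes_vcf(vcf_path)
        key = {(l.chrom, l.pos): i for i, l in enumerate(loaded_loci)}
        assert len(loaded_loci) == len(sub_loci)
        for i, loc in enumerate(sub_loci):
            j = key[(loc.chrom, loc.pos)]
            assert loaded_loci[j].derived_allele == loc.derived_allele
            np.testing.assert_array_equal(loaded.iloc[j].to_numpy(),
                                          sub.iloc[i].to_numpy())

    def test_vcf_ancestral_equal_to_alt_flips_dosage(self, tmp_path):
        # REF=G derived, ALT=A ancestral: dosage counts the REF allele
        p = tmp_path / "flip.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t100\t.\tG\tA\t.\tPASS\tAA=A\tGT\t0/0\t0/1\n")
        loci, dosages = load_genotypes_vcf(p)
        assert loci[0].ancestral_allele == "A"
        assert loci[0].derived_allele == "G"
        # s1 hom-REF(G)=2 derived copies; s2 het = 1
        assert list(dosages.iloc[0]) == [2.0, 1.0]

    def test_population_map_loading(self, tmp_path):
        p = tmp_path / "pops.tsv"
        p.write_text("# comment\ns1\tbreed_a\nw1\twolf\n")
        assert load_population_map(p) == {"s1": "breed_a", "w1": "wolf"}

    def test_dosage_table_roundtrip(self, tmp_path, geno_bundle):
        _, loci, dosages, _, _ = geno_bundle
        flat = dosages.iloc[:20].copy()
        flat.insert(0, "derived", [loci[i].derived_allele for i in range(20)])
        flat.insert(0, "ancestral", [loci[i].ancestral_allele for i in range(20)])
        flat.insert(0, "pos", [loci[i].pos + 1 for i in range(20)])
        flat.insert(0, "chrom", [loci[i].chrom for i in range(20)])
        path = tmp_path / "dosages.tsv"
        flat.to_csv(path, sep="\t", index=False)
        loaded_loci, loaded = load_dosage_table(path)
        assert loaded_loci == loci[:20]
        np.testing.assert_array_equal(loaded.to_numpy(),
                                      dosages.iloc[:20].to_numpy())
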