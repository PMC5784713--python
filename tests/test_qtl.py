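"""Genome scan, permutation thresholds, peaks, intervals and cross export."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from platephen.qtl_mapping import (GeneticMap, GenomeScanner, GenotypeMatrix,
                                   ScanError, export_rqtl_csv, find_peaks,
                                   genome_scan, genotype_probability,
                                   haldane_recombination,
                                   lod_support_interval, merge_regions,
                                   permutation_threshold, read_rqtl_csv,
                                   regression_lod, scan_with_threshold,
                                   stratified_permutation,
                                   threshold_order_statistic, load_genotypes,
                                   load_genetic_map, write_genotypes,
                                   write_genetic_map)
from platephen.synthetic_data import (CrossSimParams, PlantedQTL,
                                      simulate_cross)


def test_haldane_values():
    assert haldane_recombination(0.0) == 0.0
    assert haldane_recombination(10.0) == pytest.approx(0.09063, abs=1e-5)
    assert haldane_recombination(10000.0) > 0.4999
    with pytest.raises(ScanError):
        haldane_recombination(-1.0)


def test_genotype_probability_cases():
    assert genotype_probability(1, 1, 0.0, 0.0) == 1.0
    assert genotype_probability(None, None, 0.0, 0.0) == 0.5
    # symmetric flanks with opposite alleles give 0.5
    assert genotype_probability(1, 0, 12.0, 12.0) == pytest.approx(0.5)
    # both flanks allele 1 at r=0.1 each: 0.81/(0.81+0.01)
    d = -50.0 * math.log(1.0 - 2 * 0.1)  # distance giving r = 0.1
    assert genotype_probability(1, 1, d, d) == pytest.approx(0.81 / 0.82)
    # one-sided: probability equals the transition probability
    assert genotype_probability(1, None, d, 0.0) == pytest.approx(0.9)
    assert genotype_probability(None, 0, 0.0, d) == pytest.approx(0.1)


def test_regression_lod_worked_example():
    """Two balanced groups offset by 1: LOD = 4*log10(2.04/0.04) ~ 6.83."""
    y = [1.0, 1.1, 0.9, 1.0, 2.0, 2.1, 1.9, 2.0]
    p = [0, 0, 0, 0, 1, 1, 1, 1]
    assert regression_lod(y, p) == pytest.approx(4 * math.log10(2.04 / 0.04),
                                                 abs=1e-9)
    assert regression_lod(y, p) == pytest.approx(6.83, abs=0.005)


def test_regression_lod_matches_two_group_anova_oracle():
    """With p in {0,1} the regression LOD equals a brute-force group-mean fit."""
    rng = np.random.default_rng(17)
    for _ in range(10):
        p = rng.integers(0, 2, 20).astype(float)
        if p.min() == p.max():
            continue
        y = rng.normal(0, 1, 20) + 0.8 * p
        # oracle: residual sums of squares from explicit group means
        rss0 = np.sum((y - y.mean()) ** 2)
        rss1 = sum(np.sum((y[p == g] - y[p == g].mean()) ** 2) for g in (0, 1))
        oracle = (len(y) / 2) * math.log10(rss0 / rss1)
        assert regression_lod(y, p) == pytest.approx(oracle, abs=1e-9)


def test_regression_lod_affine_invariance_and_degenerates():
    rng = np.random.default_rng(18)
    y = rng.normal(0, 1, 30)
    p = rng.uniform(0, 1, 30)
    base = regression_lod(y, p)
    assert regression_lod(3.0 * y - 7.0, p) == pytest.approx(base, abs=1e-9)
    assert regression_lod(y, np.full(30, 0.4)) == 0.0
    with pytest.raises(ScanError):
        regression_lod(np.full(30, 1.0), p)
    assert base >= 0.0


def _small_cross(seed, effect=0.0, qtl_pos=40.0):
    rng = np.random.default_rng(seed)
    qtls = [PlantedQTL("chr01", qtl_pos, effect)] if effect else []
    params = CrossSimParams(chrom_lengths_cM=(100.0, 100.0), qtls=qtls)
    return simulate_cross(params, rng)


def test_genome_scan_finds_planted_qtl():
    """A 1-SD additive QTL at 40 cM dominates the profile within 10 cM (seed 21)."""
    geno, gmap, phen, truth = _small_cross(21, effect=1.0)
    profile = genome_scan(phen, geno, gmap)
    top = profile.loc[profile["lod"].idxmax()]
    assert top["chrom"] == "chr01"
    assert abs(top["pos_cM"] - truth["qtl_markers"][0]["pos_cM"]) <= 10.0
    assert (profile["lod"] >= 0).all()


def test_null_scan_max_lod_moderate():
    """Without a QTL the genome-wide max LOD stays in the null range (seed 22)."""
    geno, gmap, phen, _ = _small_cross(22, effect=0.0)
    profile = genome_scan(phen, geno, gmap)
    assert profile["lod"].max() < 4.0


def test_permuting_phenotype_changes_lod_not_positions():
    geno, gmap, phen, _ = _small_cross(23, effect=1.0)
    profile = genome_scan(phen, geno, gmap)
    shuffled = phen.copy()
    shuffled["value"] = np.random.default_rng(0).permutation(
        shuffled["value"].to_numpy())
    profile2 = genome_scan(shuffled, geno, gmap)
    pd.testing.assert_frame_equal(profile[["chrom", "pos_cM"]],
                                  profile2[["chrom", "pos_cM"]])
    assert not np.allclose(profile["lod"], profile2["lod"])


def test_stratified_permutation_preserves_stratum_multisets():
    rng = np.random.default_rng(31)
    y = np.arange(12, dtype=float)
    strata = np.repeat(["a", "b", "c"], 4)
    out = stratified_permutation(y, strata, rng)
    for s in "abc":
        idx = strata == s
        assert sorted(out[idx]) == sorted(y[idx])
    # all singleton strata -> identity
    np.testing.assert_array_equal(
        stratified_permutation(y, np.arange(12), rng), y)


def test_stratified_permutation_never_mixes_replicates():
    """With strata = tetrad x replicate group, values never cross between the
    two replicate groups over many draws (seed 31)."""
    rng = np.random.default_rng(31)
    y = np.concatenate([np.arange(8, dtype=float),          # replicate 1
                        100.0 + np.arange(8, dtype=float)])  # replicate 2
    tetrad = np.tile(np.repeat(["t1", "t2"], 4), 2)
    rep = np.repeat(["r1", "r2"], 8)
    strata = np.char.add(tetrad, rep)
    for _ in range(1000):
        out = stratified_permutation(y, strata, rng)
        assert out[:8].max() < 100.0 and out[8:].min() >= 100.0


def test_threshold_order_statistic_convention():
    assert threshold_order_statistic(1000, 0.05) == 951
    assert threshold_order_statistic(200, 0.05) == 191
    assert threshold_order_statistic(20, 0.05) == 20


def test_permutation_threshold_with_callable_oracle():
    """The threshold is exactly the documented order statistic of the maxima."""
    rng = np.random.default_rng(33)
    y = rng.normal(0, 1, 40)
    strata = np.zeros(40)

    maxima = []

    def fake_scan(yp):
        v = float(np.abs(yp).max())
        maxima.append(v)
        return v

    thr = permutation_threshold(y, strata, fake_scan, n_perm=50, alpha=0.05,
                                rng=rng)
    k = threshold_order_statistic(50, 0.05)
    assert thr == sorted(maxima)[k - 1]


def test_scan_with_threshold_recovers_planted_qtl_interval():
    geno, gmap, phen, truth = _small_cross(21, effect=1.2)
    res = scan_with_threshold(phen, geno, gmap, n_perm=100,
                              rng=np.random.default_rng(21))
    true_pos = truth["qtl_markers"][0]["pos_cM"]
    hits = [p for p in res.peaks
            if p.chrom == "chr01" and p.lo_cM <= true_pos <= p.hi_cM]
    assert hits, f"no peak interval covers {true_pos}; peaks={res.peaks}"
    assert all(p.lod >= res.threshold for p in res.peaks)


def test_lod_support_interval_walk():
    pos = np.arange(7, dtype=float)
    lods = np.array([0.2, 1.0, 3.0, 5.0, 3.2, 1.2, 0.5])
    # drop threshold 3.5: positions 2 and 4 are the first drop-below points
    assert lod_support_interval(pos, lods, 3) == (2.0, 4.0)
    # monotone profile peaking at the chromosome end clips there
    rising = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    assert lod_support_interval(np.arange(5.0), rising, 4) == (2.0, 4.0)
    # flat profile at peak height spans the whole chromosome
    flat = np.full(5, 3.0)
    assert lod_support_interval(np.arange(5.0), flat, 2) == (0.0, 4.0)


def test_find_peaks_cases():
    profile = pd.DataFrame({"chrom": "chr01", "pos_cM": np.arange(7.0),
                            "lod": [0.2, 1.0, 3.0, 5.0, 3.2, 1.2, 0.5]})
    assert find_peaks(profile, threshold=6.0) == []
    peaks = find_peaks(profile, threshold=3.0)
    assert len(peaks) == 1 and peaks[0].pos_cM == 3.0
    # twin peaks with overlapping intervals merge to the higher one
    twin = pd.DataFrame({"chrom": "chr01", "pos_cM": np.arange(9.0),
                         "lod": [0.5, 4.0, 5.0, 4.4, 4.2, 4.6, 4.8, 4.0, 0.5]})
    peaks = find_peaks(twin, threshold=3.5)
    assert len(peaks) == 1
    assert peaks[0].pos_cM == 2.0


def test_merge_regions():
    disjoint = [("c1", 0.0, 5.0), ("c1", 10.0, 15.0), ("c2", 0.0, 5.0)]
    assert len(merge_regions(disjoint)) == 3
    overlapping = [("c1", float(i), float(i + 10)) for i in range(6)]
    regions = merge_regions(overlapping)
    assert len(regions) == 1 and len(regions[0].members) == 6
    # chain overlap a-b, b-c with a,c disjoint still merges transitively
    chain = [("c1", 0.0, 4.0), ("c1", 3.0, 8.0), ("c1", 7.0, 12.0)]
    regions = merge_regions(chain)
    assert len(regions) == 1
    assert (regions[0].lo_cM, regions[0].hi_cM) == (0.0, 12.0)


def test_rqtl_export_layout_and_round_trip():
    geno, gmap, phen, _ = _small_cross(25)
    text = export_rqtl_csv(phen, geno, gmap)
    lines = text.splitlines()
    assert lines[0].split(",")[0] == "phenotype"
    assert lines[1].startswith(",chr01")
    assert lines[2].startswith(",0.0")
    assert len(lines) == 3 + len(phen)
    phen2, geno2, gmap2 = read_rqtl_csv(text)
    np.testing.assert_array_equal(
        geno2.table.to_numpy(),
        geno.table.loc[phen["strain"]].to_numpy())
    np.testing.assert_allclose(phen2["value"], phen["value"])
    pd.testing.assert_frame_equal(gmap2.table, gmap.table)


def test_rqtl_export_missing_genotype_becomes_empty_cell():
    geno, gmap, phen, _ = _small_cross(26)
    geno.table.iloc[0, 0] = np.nan
    row = export_rqtl_csv(phen.iloc[:1], geno, gmap).splitlines()[3]
    assert row.split(",")[1] == ""


def test_genotype_and_map_csv_round_trip():
    geno, gmap, _, _ = _small_cross(27)
    geno2 = load_genotypes(write_genotypes(geno))
    np.testing.assert_array_equal(geno2.table.to_numpy(), geno.table.to_numpy())
    assert list(geno2.meta["tetrad"]) == list(geno.meta["tetrad"])
    gmap2 = load_genetic_map(write_genetic_map(gmap))
    pd.testing.assert_frame_equal(gmap2.table, gmap.table)


def test_scan_with_missing_genotypes_conditions_on_informative_flanks():
    geno, gmap, phen, truth = _small_cross(28, effect=1.2)
    rng = np.random.default_rng(28)
    mask = rng.random(geno.table.shape) < 0.1
    geno.table.values[mask] = np.nan
    profile = genome_scan(phen, geno, gmap)
    top = profile.loc[profile["lod"].idxmax()]
    assert top["chrom"] == "chr01"
    assert abs(top["pos_cM"] - truth["qtl_markers"][0]["pos_cM"]) <= 10.0
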