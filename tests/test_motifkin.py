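"""Motif kinetics: IUPAC scanning, profile geometry, ratio of increase,
rank-sum testing against an enumeration oracle, and the native/WGA caller."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_sites
from ipdkin import (compare_native_wga, kmer_focal_table,
                    motif_profile, ratio_of_increase, scan_motif,
                    wilcoxon_ranksum)
from ipdkin.kinsim import ReferenceGenome
from ipdkin.util import revcomp


def ranksum_enumeration_p(x, y):
    """Independent oracle: two-sided p by enumerating all ways the pooled
    tie-free sample could be split into groups of the observed sizes."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    mu = len(x) * (len(pooled) + 1) / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), len(x)):
        total += 1
        if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


class TestScanMotif:
    def test_palindrome_matches_both_strands(self):
        genome = ReferenceGenome({"c": "GGATCC"})
        occ = scan_motif(genome, "GATC")
        assert sorted(zip(occ["start"], occ["strand"])) == [(1, "+"), (1, "-")]

    @pytest.mark.parametrize("seq", ["ACGCATG", "ACGCGTG"])
    def test_degenerate_r_code(self, seq):
        genome = ReferenceGenome({"c": seq})
        occ = scan_motif(genome, "ACGCRTG")
        assert (occ["strand"] == "+").sum() == 1

    def test_gapped_motif(self):
        seq = "TGA" + "ACGTACGT" + "TGCA"
        genome = ReferenceGenome({"c": seq + "TTTT"})
        occ = scan_motif(genome, "TGANNNNNNNNTGCA")
        assert (occ["start"] == 0).any()

    def test_overlapping_matches_all_reported(self):
        genome = ReferenceGenome({"c": "AAAA"})
        occ = scan_motif(genome, "AA")
        assert (occ["strand"] == "+").sum() == 3

    def test_strand_symmetry(self):
        """Scanning M yields the same minus occurrences as revcomp(M) plus."""
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), 500))
        genome = ReferenceGenome({"c": seq})
        motif = "GGWCC"
        occ = scan_motif(genome, motif)
        occ_rc = scan_motif(genome, revcomp(motif))
        minus = set(occ.loc[occ["strand"] == "-", "start"])
        plus_rc = set(occ_rc.loc[occ_rc["strand"] == "+", "start"])
        assert minus == plus_rc

    def test_invalid_iupac(self):
        genome = ReferenceGenome({"c": "ACGT"})
        with pytest.raises(ValueError, match="Q"):
            scan_motif(genome, "AQT")


class TestMotifProfile:
    def test_constant_sites_flat_profile(self):
        sites = make_sites(np.full(30, 2.0))
        occ = pd.DataFrame({"contig": ["chr1"], "start": [10],
                            "strand": ["+"]})
        prof = motif_profile(sites, occ, "GATC", flank=5)
        present = prof.table.dropna(subset=["mean_ipd"])
        assert (present["mean_ipd"] == 2.0).all()
        assert (present["se"] == 0.0).all()
        assert (present["n_sites"] == 1).all()

    def test_minus_strand_mirrors_plus_of_revcomp(self):
        """With strand-symmetric site values, the profile of a minus
        occurrence of M equals the mirrored profile of the plus occurrence
        of revcomp(M) over the same window (coordinate contract)."""
        n = 40
        both = pd.concat([make_sites(np.arange(n, dtype=float) + 1.0,
                                     strand=s) for s in "+-"],
                         ignore_index=True)
        m = 4
        occ_minus = pd.DataFrame({"contig": ["chr1"], "start": [12],
                                  "strand": ["-"]})
        occ_plus = pd.DataFrame({"contig": ["chr1"], "start": [12],
                                 "strand": ["+"]})
        prof_minus = motif_profile(both, occ_minus, "GAGG", flank=3)
        prof_plus = motif_profile(both, occ_plus, revcomp("GAGG"), flank=3)
        a = prof_minus.table.set_index("rel_pos")["mean_ipd"]
        mirrored = (prof_plus.table
                    .assign(rel_pos=lambda t: m - 1 - t["rel_pos"])
                    .set_index("rel_pos")["mean_ipd"])
        for rel in a.index:
            assert a.loc[rel] == pytest.approx(mirrored.loc[rel])

    def test_flanks_off_contig_contribute_nothing(self):
        sites = make_sites(np.full(8, 2.0))
        occ = pd.DataFrame({"contig": ["chr1"], "start": [1],
                            "strand": ["+"]})
        prof = motif_profile(sites, occ, "GA", flank=5)
        left_tail = prof.table[prof.table["rel_pos"] < -1]
        assert (left_tail["n_sites"] == 0).all()

    def test_no_usable_sites_raises(self):
        sites = make_sites(np.full(5, 2.0))
        occ = pd.DataFrame({"contig": ["chr2"], "start": [0],
                            "strand": ["+"]})
        with pytest.raises(ValueError, match="no site kinetics"):
            motif_profile(sites, occ, "GATC")


class TestWilcoxonRanksum:
    def test_canonical_exact_case(self):
        _, p = wilcoxon_ranksum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_strong_separation(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0.0, 1.0, 50)
        _, p = wilcoxon_ranksum(x, x + 10.0)  # disjoint supports
        assert p < 1e-6

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (3, 5),
                                       (4, 4), (5, 3)])
    def test_exact_path_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.7)
            x, y = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_ranksum(x, y)
            assert p == pytest.approx(ranksum_enumeration_p(x, y))

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (6, 8),
                                       (8, 8)])
    def test_normal_path_close_to_exact(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            _, p_exact = wilcoxon_ranksum(x, y, method="exact")
            _, p_norm = wilcoxon_ranksum(x, y, method="normal")
            assert abs(p_norm - p_exact) < 0.02

    def test_tie_corrected_variance_handles_heavy_ties(self):
        x = [1.0] * 10 + [2.0] * 10
        y = [1.0] * 10 + [2.0] * 5
        _, p = wilcoxon_ranksum(x, y)
        assert 0.0 < p <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestRatioOfIncrease:
    def test_simple_ratio(self):
        genome_sites = make_sites(np.ones(200))
        occ = pd.DataFrame({"contig": ["chr1"] * 3, "start": [5, 50, 100],
                            "strand": ["+"] * 3})
        boosted = genome_sites.copy()
        boosted.loc[boosted["pos"].isin([5, 50, 100]), "mean_ipd"] = 2.0
        prof = motif_profile(boosted, occ, "A", flank=0)
        (stat,) = ratio_of_increase(prof, boosted, 0)
        assert stat.focal_base == "A"
        assert stat.ratio_of_increase == pytest.approx(
            2.0 / boosted["mean_ipd"].mean())

    def test_null_data_ratio_near_one(self, null_sites, null_genome):
        occ = scan_motif(null_genome, "GATC")
        prof = motif_profile(null_sites, occ, "GATC")
        (stat,) = ratio_of_increase(prof, null_sites, 1)
        assert stat.focal_base == "A"
        assert stat.ratio_of_increase == pytest.approx(1.0, abs=0.05)

    def test_context_multiplier_recovered(self, gatc_dataset):
        """A 1.03x sequence-context boost at the GATC adenine shows up as a
        ~1.03 ratio of increase in the modification-free WGA sample."""
        sites = gatc_dataset["wga_sites"]
        loci = gatc_dataset["loci"]
        occ = pd.DataFrame({"contig": loci["contig"],
                            "start": loci["pos"] - 1,
                            "strand": loci["strand"]})
        occ = occ[loci["strand"] == "+"].reset_index(drop=True)
        prof = motif_profile(sites, occ, "GATC")
        (stat,) = ratio_of_increase(prof, sites, 1)
        assert stat.ratio_of_increase == pytest.approx(1.03, abs=0.03)


class TestCompareNativeWga:
    def test_identical_tables(self, null_sites):
        loci = null_sites[["contig", "pos", "strand"]].head(100)
        stat = compare_native_wga(null_sites, null_sites, loci)
        assert stat.native_wga_fold == 1.0
        assert stat.native_wga_p == pytest.approx(1.0, abs=0.05)

    def test_modification_fold_recovered(self, gatc_dataset):
        stat = compare_native_wga(gatc_dataset["native_sites"],
                                  gatc_dataset["wga_sites"],
                                  gatc_dataset["loci"])
        assert stat.native_wga_fold == pytest.approx(8.57, rel=0.10)
        assert stat.native_wga_p < 1e-6
        assert stat.focal_base == "A"

    def test_no_shared_loci_raises(self, null_sites):
        loci = pd.DataFrame({"contig": ["nope"], "pos": [0],
                             "strand": ["+"]})
        with pytest.raises(ValueError, match="shared"):
            compare_native_wga(null_sites, null_sites, loci)


class TestKmerFocalTable:
    def test_two_mer_universe(self, null_sites, null_genome):
        table = kmer_focal_table(null_sites, null_genome, k=2,
                                 focal_index=1, focal_base="A")
        assert table["kmer"].tolist() == ["AA", "CA", "GA", "TA"]
        assert (table["n"] > 0).all()

    def test_uniform_null_rows_near_base_mean(self, null_sites, null_genome):
        table = kmer_focal_table(null_sites, null_genome, k=2,
                                 focal_index=1, focal_base="A")
        a_mean = null_sites.loc[null_sites["ref_base"] == "A",
                                "mean_ipd"].mean()
        assert np.allclose(table["mean_focal_ipd"], a_mean, rtol=0.05)

    def test_planted_context_dominates_row(self):
        """A context multiplier planted on GA only makes the GA row mean the
        strict maximum among NA rows."""
        from ipdkin import (KineticsModelConfig, PlantSpec, aggregate_sites,
                            generate_genome, simulate_reads)
        spec = PlantSpec("GA", 1, count=80, context_multipliers={1: 2.0})
        genome, planted = generate_genome(15_000, 0.4, [spec], seed=301)
        config = KineticsModelConfig()
        sites = aggregate_sites(simulate_reads(genome, planted, config,
                                               mode="wga", seed=302))
        table = kmer_focal_table(sites, genome, k=2, focal_index=1,
                                 focal_base="A").set_index("kmer")
        ga = table.loc["GA", "mean_focal_ipd"]
        others = table.drop(index="GA")["mean_focal_ipd"]
        assert (ga > others).all()

    def test_focal_index_bounds(self, null_sites, null_genome):
        with pytest.raises(ValueError):
            kmer_focal_table(null_sites, null_genome, k=2, focal_index=2,
                             focal_base="A")
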