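"""Positional classes A-F, nearest-gene distances, the random-placement null
and its KS comparison.  Distance oracles are brute-force base counting."""

import numpy as np
import pytest

from titmine.annotate import (
    annotate,
    binned_density,
    calls_frame,
    classify_contig,
    interval_distance,
    ks_two_sample,
    nearest_gene,
    proximal_fraction,
    proximity_table,
    simulate_null_distances,
)
from titmine.models import ContigAlignment, Feature, Gene, GenomeAnnotation


def _gene(gid="g1", chrom="chr1", start=1000, end=2000, strand="+", features=None):
    if features is None:
        features = (Feature("exon", start, end, 1),)
    return Gene(id=gid, chromosome=chrom, strand=strand, start=start, end=end,
                features=features)


def _genome(genes, chrom_len=100_000):
    chroms = {c: chrom_len for c in {g.chromosome for g in genes}} or {"chr1": chrom_len}
    return GenomeAnnotation(chromosomes=chroms, genes=list(genes))


def _aln(s, e, cid="c1", chrom="chr1"):
    return ContigAlignment(contig_id=cid, chromosome=chrom, start=s, end=e)


def _brute_distance(a, b):
    """Count bases strictly between two closed intervals."""
    (a0, a1), (b0, b1) = a, b
    return sum(1 for x in range(min(a0, b0), max(a1, b1) + 1)
               if not (a0 <= x <= a1) and not (b0 <= x <= b1)
               and min(a1, b1) < x < max(a0, b0))


class TestNearestGene:
    def test_overlap_gives_zero(self):
        genome = _genome([_gene()])
        _, d = nearest_gene(_aln(1500, 1600), genome)
        assert d == 0

    @pytest.mark.parametrize("gene_iv,contig_iv,expected", [
        ((1000, 2000), (2500, 3000), 499),
        ((5000, 6000), (1000, 1500), 3499),
        ((1000, 2000), (2001, 2100), 0),  # touching, no intervening base
    ])
    def test_hand_distances(self, gene_iv, contig_iv, expected):
        genome = _genome([_gene(start=gene_iv[0], end=gene_iv[1])])
        _, d = nearest_gene(_aln(*contig_iv), genome)
        assert d == expected
        assert d == _brute_distance(gene_iv, contig_iv)

    def test_distance_matches_brute_force_on_random_intervals(self, rng):
        for _ in range(200):
            a = sorted(rng.integers(1, 5000, size=2))
            b = sorted(rng.integers(1, 5000, size=2))
            assert interval_distance(a[0], a[1], b[0], b[1]) == \
                _brute_distance((a[0], a[1]), (b[0], b[1]))

    def test_tie_broken_by_lower_start(self):
        g1 = _gene("gB", start=3000, end=4000)
        g2 = _gene("gA", start=1000, end=2000)
        genome = _genome([g1, g2])
        gene, d = nearest_gene(_aln(2400, 2600), genome)
        assert d == 399
        assert gene.id == "gA"

    def test_geneless_chromosome_reports_missing(self):
        genome = GenomeAnnotation(chromosomes={"chr1": 5000, "chr2": 5000},
                                  genes=[_gene(chrom="chr2")])
        gene, d = nearest_gene(_aln(10, 20, chrom="chr1"), genome)
        assert gene is None and d is None


class TestClassify:
    def test_downstream_flanking_is_class_a(self):
        gene = _gene()
        call = classify_contig(_aln(2500, 3000), gene)
        assert call.klass == "A" and call.distance == 499
        assert call.start_feature is None and call.end_feature is None

    def test_upstream_flanking_is_class_b(self):
        call = classify_contig(_aln(100, 300), _gene())
        assert call.klass == "B"

    def test_contig_spanning_single_exon_gene_is_class_e(self):
        gene = _gene(start=1000, end=1100)
        call = classify_contig(_aln(900, 1400), gene)
        assert call.klass == "E"

    def test_downstream_overlap_starts_in_final_exon(self):
        # plus-strand gene: 5'UTR, exon1, intron1, exon2, 3'UTR; final exon
        # is [1800, 1950]; a contig entering there and running past the gene
        # end is class C anchored in the final exon
        feats = (Feature("five_prime_UTR", 1000, 1099, 1),
                 Feature("exon", 1100, 1399, 1),
                 Feature("intron", 1400, 1799, 1),
                 Feature("exon", 1800, 1950, 2),
                 Feature("three_prime_UTR", 1951, 2000, 1))
        gene = _gene(features=feats)
        call = classify_contig(_aln(1900, 2600), gene)
        assert call.klass == "C"
        assert call.start_feature == ("exon", 2)
        assert call.end_feature is None
        assert gene.n_features("exon") == call.start_feature[1]  # final exon

    def test_upstream_overlap_ends_in_first_exon(self):
        feats = (Feature("five_prime_UTR", 1000, 1099, 1),
                 Feature("exon", 1100, 1399, 1),
                 Feature("intron", 1400, 1799, 1),
                 Feature("exon", 1800, 1950, 2),
                 Feature("three_prime_UTR", 1951, 2000, 1))
        call = classify_contig(_aln(700, 1200), _gene(features=feats))
        assert call.klass == "D"
        assert call.end_feature == ("exon", 1)

    def test_contig_inside_intron_is_class_f_intron_only(self):
        feats = (Feature("five_prime_UTR", 1000, 1099, 1),
                 Feature("exon", 1100, 1199, 1),
                 Feature("intron", 1200, 1599, 1),
                 Feature("exon", 1600, 1699, 2),
                 Feature("intron", 1700, 1899, 2),
                 Feature("exon", 1900, 1949, 3),
                 Feature("three_prime_UTR", 1950, 2000, 1))
        call = classify_contig(_aln(1750, 1850), _gene(features=feats))
        assert call.klass == "F"
        assert call.start_feature == ("intron", 2)
        assert call.end_feature == ("intron", 2)

    def test_classification_is_total_and_exclusive(self, rng):
        gene = _gene()
        for _ in range(300):
            s, e = sorted(rng.integers(1, 3500, size=2))
            call = classify_contig(_aln(int(s), int(e)), gene)
            assert call.klass in set("ABCDEF")
            assert (call.distance == 0) == (call.klass in set("CDEF")) or \
                call.klass in ("A", "B")

    def test_translation_invariance(self, rng):
        shift = 10_000
        for _ in range(100):
            s, e = sorted(int(x) for x in rng.integers(1, 3500, size=2))
            gene0 = _gene()
            gene1 = _gene(start=1000 + shift, end=2000 + shift, features=(
                Feature("exon", 1000 + shift, 2000 + shift, 1),))
            c0 = classify_contig(_aln(s, e), gene0)
            c1 = classify_contig(_aln(s + shift, e + shift), gene1)
            assert (c0.klass, c0.distance) == (c1.klass, c1.distance)


class TestNullSimulation:
    def _toy_genome(self):
        gene = _gene(start=41, end=60, features=(Feature("exon", 41, 60, 1),))
        return GenomeAnnotation(chromosomes={"chr1": 100}, genes=[gene])

    def test_fully_genic_genome_gives_all_zero(self):
        gene = _gene(start=1, end=100, features=(Feature("exon", 1, 100, 1),))
        genome = GenomeAnnotation(chromosomes={"chr1": 100}, genes=[gene])
        d = simulate_null_distances([10], genome, n_replicates=500, seed=0)
        assert (d == 0).all()

    def test_toy_distribution_matches_exhaustive_enumeration(self):
        """100-bp chromosome, gene [41,60], unit contigs: the simulated
        distance distribution must match the exact enumeration over the 100
        possible placements within 3 SE at n = 10,000."""
        genome = self._toy_genome()
        n = 10_000
        sample = simulate_null_distances([1], genome, n_replicates=n, seed=42)
        exact = {}
        for pos in range(1, 101):
            d = interval_distance(pos, pos, 41, 60)
            exact[d] = exact.get(d, 0) + 1 / 100
        # 20 overlapping + 2 touching placements report distance 0
        assert exact[0] == pytest.approx(0.22)
        for d, p in exact.items():
            observed = (sample == d).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * se + 1e-12, (d, observed, p)

    def test_fixed_seed_reproducible(self):
        genome = self._toy_genome()
        a = simulate_null_distances([1, 5], genome, n_replicates=1000, seed=7)
        b = simulate_null_distances([1, 5], genome, n_replicates=1000, seed=7)
        assert (a == b).all()

    def test_contig_longer_than_every_chromosome_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_distances([500], self._toy_genome(), n_replicates=10, seed=0)


class TestKs:
    def test_identical_samples_give_zero(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_fully_separated_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_half_overlap(self):
        d, _ = ks_two_sample([1, 2], [1, 3])
        assert d == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBinnedDensity:
    def test_single_alignment_single_bin(self):
        genome = _genome([_gene()], chrom_len=2_000_000)
        bins = binned_density([_aln(100, 200)], genome)
        assert bins["count"].sum() == 1
        assert (bins["count"] > 0).sum() == 1

    def test_bin_edges_left_closed(self):
        genome = _genome([_gene()], chrom_len=2_000_000)
        bins = binned_density([_aln(1, 50), _aln(500_001, 500_050)], genome)
        nonzero = bins[bins["count"] > 0].reset_index(drop=True)
        assert list(nonzero["bin_start"]) == [1, 500_001]
        assert list(nonzero["count"]) == [1, 1]

    def test_empty_input_all_zero(self):
        genome = _genome([_gene()])
        assert binned_density([], genome)["count"].sum() == 0

    def test_depth_weights(self):
        genome = _genome([_gene()], chrom_len=2_000_000)
        bins = binned_density([_aln(100, 200, cid="x")], genome,
                              weights={"x": 17.0})
        assert bins["count"].sum() == 17.0


class TestProximityTable:
    def test_overlapping_calls_excluded(self):
        genome = _genome([_gene()])
        calls = annotate([_aln(1500, 1600)], genome)
        table = proximity_table(calls)
        assert table["total"].sum() == 0

    def test_flanking_share_from_printed_counts(self):
        frac = proximal_fraction([5843, 5708], [19_357, 19_721])
        assert frac == pytest.approx(0.296, abs=0.005)

    def test_near_contigs_land_in_first_bin(self):
        from titmine.simulate import SimulationConfig, generate_contigs, generate_genome

        mixture = {"mRNA": 0.0, "pre_mRNA": 0.0, "intergenic_near": 1.0,
                   "intergenic_far": 0.0}
        cfg = SimulationConfig(seed=13, n_contigs=80, class_mixture=mixture,
                               near_distance=2000)
        rng = cfg.rng()
        genome = generate_genome(cfg, rng)
        _, alignments, _ = generate_contigs(genome, cfg, rng)
        calls = annotate(alignments, genome)
        table = proximity_table(calls).set_index("class")
        assert table["total"].sum() == 80
        assert (table["<2500"] == table["total"]).all()


def test_calls_frame_columns(dataset):
    calls = annotate(dataset["alignments"][:30], dataset["genome"])
    frame = calls_frame(calls)
    assert list(frame.columns) == ["contig_id", "nearest_gene_id", "distance",
                                   "class", "start_feature", "end_feature"]
    assert frame["class"].isin(list("ABCDEF")).all()
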