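"""The hierarchical SNP cascade, remap confirmation, coding-effect calls and
SNP-string detection, checked against direct rule application."""

import numpy as np
import pandas as pd
import pytest

from titmine.simulate import SimulationConfig, generate_snp_candidates
from titmine.variants import (
    coding_effect,
    confirm_by_remap,
    detect_snp_strings,
    filter_snps,
    kept_to_vcf_like,
    string_report,
)


def _cand(contig="c1", position=500, ref="A", alt="G", depth=30, minor=6,
          quality=40, neighbour=30, indel=False):
    return {"contig_id": contig, "position": position, "ref_allele": ref,
            "alt_allele": alt, "depth": depth, "minor_count": minor,
            "snp_quality": quality, "min_neighbour_quality": neighbour,
            "is_indel": indel}


def _table(rows):
    return pd.DataFrame(rows).sort_values(["contig_id", "position"]).reset_index(drop=True)


LENGTHS = {"c1": 1000, "c2": 1000}


class TestCascade:
    def test_low_maf_in_depth_band_removed(self):
        report = filter_snps(_table([_cand(depth=10, minor=2)]), LENGTHS, "modest")
        assert report.table.loc[0, "reason"] == "low_maf"

    def test_minor_count_tier_split(self):
        row = _cand(depth=30, minor=4)
        modest = filter_snps(_table([row]), LENGTHS, "modest")
        high = filter_snps(_table([row]), LENGTHS, "high")
        assert modest.table.loc[0, "fate"] == "kept_modest"
        assert high.table.loc[0, "reason"] == "low_minor_count"

    def test_proximity_distance_tiers(self):
        rows = [_cand(position=500), _cand(position=545)]  # 45 bp apart
        modest = filter_snps(_table(rows), LENGTHS, "modest")
        high = filter_snps(_table(rows), LENGTHS, "high")
        assert (modest.table["fate"] == "kept_modest").all()   # 45 >= 40
        assert (high.table["reason"] == "near_polymorphism").all()  # 45 < 50

    def test_empty_table(self):
        report = filter_snps(pd.DataFrame(columns=list(_cand())), LENGTHS, "high")
        assert report.table.empty and report.kept.empty

    @pytest.mark.parametrize("row,reason", [
        (_cand(quality=30), "low_quality"),
        (_cand(neighbour=20), "low_quality"),
        (_cand(indel=True), "indel"),
        (_cand(depth=7, minor=3), "low_depth"),
        (_cand(position=30), "near_contig_end"),
        (_cand(position=980), "near_contig_end"),
    ])
    def test_single_rule_violations(self, row, reason):
        report = filter_snps(_table([row]), LENGTHS, "modest")
        assert report.table.loc[0, "reason"] == reason

    def test_quality_passing_indel_participates_in_proximity(self):
        # the indel itself is removed as an indel, but it still knocks out a
        # clean SNP 30 bp away at modest stringency (simultaneous step 6)
        rows = [_cand(position=500, indel=True), _cand(position=530)]
        report = filter_snps(_table(rows), LENGTHS, "modest")
        fates = report.table.set_index("position")
        assert fates.loc[500, "reason"] == "indel"
        assert fates.loc[530, "reason"] == "near_polymorphism"

    def test_quality_failing_indel_does_not(self):
        rows = [_cand(position=500, indel=True, quality=10), _cand(position=530)]
        report = filter_snps(_table(rows), LENGTHS, "modest")
        fates = report.table.set_index("position")
        assert fates.loc[500, "reason"] == "low_quality"
        assert fates.loc[530, "fate"] == "kept_modest"

    def test_high_survivor_can_vanish_from_modest_file(self):
        # X clean; Y (minor 4) dies at step 5 only at high stringency, so X
        # is isolated at high but gains a <40 bp neighbour at modest
        rows = [_cand(position=500), _cand(position=530, minor=4)]
        high = filter_snps(_table(rows), LENGTHS, "high").table.set_index("position")
        modest = filter_snps(_table(rows), LENGTHS, "modest").table.set_index("position")
        assert high.loc[500, "fate"] == "kept_high"
        assert modest.loc[500, "reason"] == "near_polymorphism"

    def test_pre_proximity_high_survivors_subset_of_modest(self, dataset):
        cands = dataset["candidates"].drop(columns="is_true")
        lengths = {c.id: c.length for c in dataset["contigs"]}
        pre_reasons = {"low_quality", "indel", "low_depth", "low_maf",
                       "low_minor_count"}
        out = {}
        for tier in ("high", "modest"):
            t = filter_snps(cands, lengths, tier).table
            alive = ~t["reason"].isin(pre_reasons) & ~t["is_indel"]
            out[tier] = set(zip(t.loc[alive, "contig_id"], t.loc[alive, "position"]))
        assert out["high"] <= out["modest"]

    def test_reason_counts_conserve_input(self, dataset):
        cands = dataset["candidates"].drop(columns="is_true")
        lengths = {c.id: c.length for c in dataset["contigs"]}
        for tier in ("high", "modest"):
            report = filter_snps(cands, lengths, tier)
            assert len(report.kept) + int((report.table["reason"] != "").sum()) \
                == len(cands)
            assert (report.table.loc[report.table["fate"] == "removed",
                                     "reason"] != "").all()

    def test_position_beyond_contig_rejected(self):
        with pytest.raises(ValueError):
            filter_snps(_table([_cand(position=2000)]), LENGTHS, "modest")


class TestRemap:
    def test_identical_sets_fully_confirmed(self):
        t = _table([_cand(position=p) for p in (100, 300, 500)])
        confirmed, frac = confirm_by_remap(t, t)
        assert frac == 1.0 and len(confirmed) == 3

    def test_missing_site_excluded(self):
        t = _table([_cand(position=p) for p in (100, 300, 500)])
        confirmed, frac = confirm_by_remap(t, t.iloc[:2])
        assert len(confirmed) == 2 and frac == pytest.approx(2 / 3)

    def test_allele_mismatch_not_confirmed(self):
        t = _table([_cand(position=100, alt="G")])
        remap = _table([_cand(position=100, alt="T")])
        confirmed, _ = confirm_by_remap(t, remap)
        assert confirmed.empty

    def test_remap_dropping_artifacts_recovers_truth(self, dataset):
        cands = dataset["candidates"]
        lengths = {c.id: c.length for c in dataset["contigs"]}
        kept = filter_snps(cands.drop(columns="is_true"), lengths, "modest").kept
        remap = cands[cands["is_true"]].drop(columns="is_true")
        confirmed, _ = confirm_by_remap(kept, remap)
        key = ["contig_id", "position"]
        truth_keys = set(map(tuple, remap[key].itertuples(index=False)))
        confirmed_keys = set(map(tuple, confirmed[key].itertuples(index=False)))
        assert confirmed_keys <= truth_keys


class TestCodingEffect:
    @pytest.mark.parametrize("codon,pos,alt,expected", [
        ("GGG", 3, "A", "synonymous"),      # Gly -> Gly (wobble)
        ("ATG", 3, "A", "non-synonymous"),  # Met -> Ile
        ("AAA", 1, "G", "non-synonymous"),  # Lys -> Glu
        ("CTG", 1, "T", "synonymous"),      # Leu -> Leu
    ])
    def test_examples(self, codon, pos, alt, expected):
        assert coding_effect(codon, pos, alt) == expected

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            coding_effect("ANG", 2, "T")


class TestSnpStrings:
    def test_maximally_spread_five_string_spans_33_not_flagged(self):
        strings, flagged = detect_snp_strings([1, 9, 17, 25, 33])
        assert len(strings) == 1 and len(strings[0]) == 5
        assert strings[0][-1] - strings[0][0] + 1 == 33
        assert not flagged

    def test_single_snp_no_string(self):
        strings, flagged = detect_snp_strings([42])
        assert strings == [] and not flagged

    def test_mixed_runs_flag_on_six(self):
        strings, flagged = detect_snp_strings([1, 5, 30, 33, 36, 39, 42, 45])
        assert [len(s) for s in strings] == [2, 6]
        assert flagged

    def test_offset_nine_breaks_a_string(self):
        strings, _ = detect_snp_strings([1, 10])
        assert strings == []

    def test_strings_partition_their_members(self, rng):
        positions = np.unique(rng.integers(1, 2000, size=300))
        strings, _ = detect_snp_strings(list(positions))
        seen = [p for s in strings for p in s]
        assert len(seen) == len(set(seen))
        for s in strings:
            assert all(b - a <= 8 for a, b in zip(s, s[1:]))

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            detect_snp_strings([5, 1])

    def test_report_over_table(self):
        rows = [_cand(position=p) for p in (1, 9, 17, 25, 33, 41)]
        report = string_report(_table(rows))
        assert report.loc[0, "longest_string"] == 6
        assert bool(report.loc[0, "splice_candidate"])


def test_sensitivity_and_leakage_on_synthetic_table(dataset):
    """At modest stringency, >= 95% of planted true SNPs survive and <= 5%
    of planted artifacts leak through."""
    cands = dataset["candidates"]
    lengths = {c.id: c.length for c in dataset["contigs"]}
    report = filter_snps(cands.drop(columns="is_true"), lengths, "modest")
    table = report.table.assign(is_true=cands["is_true"].to_numpy())
    true = table[table["is_true"]]
    art = table[~table["is_true"]]
    assert len(true) > 100 and len(art) > 100
    sensitivity = (true["fate"] == "kept_modest").mean()
    leakage = (art["fate"] == "kept_modest").mean()
    assert sensitivity >= 0.95
    assert leakage <= 0.05


def test_vcf_like_output(dataset):
    cands = dataset["candidates"].drop(columns="is_true")
    lengths = {c.id: c.length for c in dataset["contigs"]}
    report = filter_snps(cands, lengths, "high")
    vcf = kept_to_vcf_like(report)
    assert list(vcf.columns) == ["CHROM", "POS", "REF", "ALT", "INFO"]
    assert len(vcf) == len(report.kept)
    assert vcf["INFO"].str.contains("TIER=high").all()
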