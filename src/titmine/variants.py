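"""Hierarchical SNP-quality filtering, remap confirmation, coding-effect
calls, and SNP-string splice-candidate detection.

The cascade screens a candidate table in a fixed order, recording the first
failing rule for every removal:

1. quality: base-call quality > 30 and the minimum quality of the six
   neighbouring bases (three per side) > 20;
2. indels dropped (but indels passing the quality screen still participate in
   the proximity computation of step 6);
3. read depth < 8 dropped;
4. at depth 8-20, minor allele frequency < 25% dropped (strict);
5. at depth > 20, minor allele count below the tier threshold dropped
   (5 for "high" stringency, 3 for "modest");
6. among the survivors of 1-5 plus quality-passing indels, every site with
   another polymorphism within the tier distance (50 bp high / 40 bp modest,
   positional offset, strict) or that close to a contig end is removed.
   Step 6 is simultaneous, not cascading: removals are computed against the
   full pre-step-6 polymorphism set, which is why a site kept at high
   stringency can disappear from the modest file once lower-stringency
   neighbours enter the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

STRINGENCY = {
    "high": {"min_minor_count": 5, "proximity": 50},
    "modest": {"min_minor_count": 3, "proximity": 40},
}
MIN_SNP_QUALITY = 30
MIN_NEIGHBOUR_QUALITY = 20
MIN_DEPTH = 8
MAF_DEPTH_BAND = (8, 20)  # closed band for the MAF rule
MIN_MAF = 0.25
STRING_MAX_OFFSET = 8  # < 8 intervening bases between consecutive string SNPs
STRING_MIN_SNPS = 6

REMOVAL_REASONS = (
    "low_quality", "indel", "low_depth", "low_maf", "low_minor_count",
    "near_polymorphism", "near_contig_end",
)


@dataclass
class FilterReport:
    """Per-candidate fate plus audit counts; fates partition the input."""

    table: pd.DataFrame  # input columns + 'fate' and 'reason'
    stringency: str

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["fate"] == f"kept_{self.stringency}"]

    @property
    def counts(self) -> pd.Series:
        return self.table["reason"].value_counts()


def filter_snps(candidates: pd.DataFrame, contig_lengths: dict[str, int],
                stringency: str) -> FilterReport:
    """Run the cascade at one stringency tier; see the module docstring."""
    if stringency not in STRINGENCY:
        raise ValueError(f"stringency must be one of {sorted(STRINGENCY)}")
    params = STRINGENCY[stringency]
    df = candidates.copy().reset_index(drop=True)
    if df.empty:
        df["fate"] = pd.Series(dtype=str)
        df["reason"] = pd.Series(dtype=str)
        return FilterReport(table=df, stringency=stringency)
    for cid, pos in zip(df["contig_id"], df["position"]):
        if pos < 1 or pos > contig_lengths[cid]:
            raise ValueError(f"SNP position {pos} outside contig {cid}")

    depth = df["depth"].to_numpy()
    minor = df["minor_count"].to_numpy()
    reason = np.full(len(df), "", dtype=object)
    quality_ok = (df["snp_quality"].to_numpy() > MIN_SNP_QUALITY) & \
                 (df["min_neighbour_quality"].to_numpy() > MIN_NEIGHBOUR_QUALITY)
    reason[~quality_ok] = "low_quality"
    is_indel = df["is_indel"].astype(bool).to_numpy()
    step2 = quality_ok & is_indel
    reason[step2] = "indel"
    alive = quality_ok & ~is_indel
    low_depth = alive & (depth < MIN_DEPTH)
    reason[low_depth] = "low_depth"
    alive &= ~low_depth
    in_band = (depth >= MAF_DEPTH_BAND[0]) & (depth <= MAF_DEPTH_BAND[1])
    low_maf = alive & in_band & (minor / depth < MIN_MAF)
    reason[low_maf] = "low_maf"
    alive &= ~low_maf
    low_minor = alive & (depth > MAF_DEPTH_BAND[1]) & \
        (minor < params["min_minor_count"])
    reason[low_minor] = "low_minor_count"
    alive &= ~low_minor

    # step 6: simultaneous proximity screen over survivors + surviving indels
    poly = alive | step2
    dist = params["proximity"]
    near_poly = np.zeros(len(df), dtype=bool)
    near_end = np.zeros(len(df), dtype=bool)
    for cid, idx in df.loc[poly].groupby("contig_id").groups.items():
        positions = df.loc[idx, "position"].to_numpy()
        order = np.argsort(positions)
        sidx = np.asarray(idx)[order]
        spos = positions[order]
        gaps = np.diff(spos)
        close = np.zeros(len(spos), dtype=bool)
        close[:-1] |= gaps < dist
        close[1:] |= gaps < dist
        near_poly[sidx[close]] = True
        L = contig_lengths[cid]
        near_end[sidx[(spos - 1 < dist) | (L - spos < dist)]] = True
    flag_poly = alive & near_poly
    reason[flag_poly] = "near_polymorphism"
    alive &= ~near_poly
    flag_end = alive & near_end
    reason[flag_end] = "near_contig_end"
    alive &= ~near_end

    fate = np.where(alive, f"kept_{stringency}", "removed")
    df["fate"] = fate
    df["reason"] = np.where(alive, "", reason)
    assert int(alive.sum()) + int((df["reason"] != "").sum()) == len(df)
    return FilterReport(table=df, stringency=stringency)


def confirm_by_remap(primary: pd.DataFrame, remap: pd.DataFrame
                     ) -> tuple[pd.DataFrame, float]:
    """Keep primary SNPs redetected in the remap assembly.

    Matching requires identical contig, position and alleles.  Returns the
    confirmed subset and the retention fraction.
    """
    key = ["contig_id", "position", "ref_allele", "alt_allele"]
    if primary.empty:
        return primary, float("nan")
    remap_keys = set(map(tuple, remap[key].itertuples(index=False)))
    mask = [tuple(row) in remap_keys
            for row in primary[key].itertuples(index=False)]
    confirmed = primary[mask]
    return confirmed, len(confirmed) / len(primary)


_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


def coding_effect(codon: str, codon_position: int, alt_base: str) -> str:
    """'synonymous' or 'non-synonymous' under the standard genetic code."""
    codon = codon.upper()
    alt_base = alt_base.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon) or alt_base not in "ACGT":
        raise ValueError("ambiguous or invalid base in codon/alt")
    if codon_position not in (1, 2, 3):
        raise ValueError("codon_position must be 1-3")
    alt_codon = codon[:codon_position - 1] + alt_base + codon[codon_position:]
    return "synonymous" if _translate(codon) == _translate(alt_codon) else "non-synonymous"


def detect_snp_strings(positions, max_offset: int = STRING_MAX_OFFSET,
                       min_string: int = STRING_MIN_SNPS
                       ) -> tuple[list[list[int]], bool]:
    """Group sorted SNP positions into proximity 'strings'.

    Two or more SNPs form a string when consecutive members have fewer than
    ``max_offset`` intervening bases (positional offset <= ``max_offset``);
    a string of five can therefore span at most ``4 * max_offset + 1 = 33``
    bases at the default.  The flag is set when any string reaches
    ``min_string`` members — the splice-variant signature.
    """
    pos = list(positions)
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be sorted ascending")
    strings: list[list[int]] = []
    run = [pos[0]] if pos else []
    for p in pos[1:]:
        if p - run[-1] <= max_offset:
            run.append(p)
        else:
            if len(run) >= 2:
                strings.append(run)
            run = [p]
    if len(run) >= 2:
        strings.append(run)
    flagged = any(len(s) >= min_string for s in strings)
    return strings, flagged


def string_report(candidates: pd.DataFrame, max_offset: int = STRING_MAX_OFFSET,
                  min_string: int = STRING_MIN_SNPS) -> pd.DataFrame:
    """Per-contig string detection over a raw (unfiltered) candidate table."""
    rows = []
    for cid, grp in candidates.groupby("contig_id"):
        positions = sorted(grp["position"])
        strings, flagged = detect_snp_strings(positions, max_offset, min_string)
        rows.append({"contig_id": cid, "n_snps": len(positions),
                     "n_strings": len(strings),
                     "longest_string": max((len(s) for s in strings), default=0),
                     "splice_candidate": flagged})
    return pd.DataFrame(rows, columns=["contig_id", "n_snps", "n_strings",
                                       "longest_string", "splice_candidate"])


def kept_to_vcf_like(report: FilterReport) -> pd.DataFrame:
    """Minimal VCF-like TSV of kept SNPs (CHROM=contig, POS, REF, ALT, INFO)."""
    kept = report.kept
    return pd.DataFrame({
        "CHROM": kept["contig_id"],
        "POS": kept["position"],
        "REF": kept["ref_allele"],
        "ALT": kept["alt_allele"],
        "INFO": [
            f"DP={d};MC={m};TIER={report.stringency}"
            for d, m in zip(kept["depth"], kept["minor_count"])
        ],
    })
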