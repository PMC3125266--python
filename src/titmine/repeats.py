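"""Scored scanning for 2-5 bp tandem repeats (microsatellites/SSRs).

A seed unit of length k anchors each candidate locus; extension compares every
subsequent base with the corresponding base of the seed unit, scoring +1 for a
match and -6 for a mismatch (N never matches).  The seed unit itself scores 0.
Extension stops when the running score drops below zero or the sequence ends,
and the locus is trimmed back to its maximum-score prefix.  A locus is
reported when its score reaches 6 and it contains at least 5 complete units.
Mononucleotide and self-periodic units are never reported; overlapping
candidates are deduplicated keeping the highest score, then the longest span,
then the smallest unit length.  Reported units are canonicalised to the
lexicographically smallest rotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import RepeatHit

UNIT_LENGTHS = (2, 3, 4, 5)
MATCH_SCORE = 1
MISMATCH_PENALTY = -6
MIN_SCORE = 6
MIN_UNITS = 5
REPEAT_BINS = ((5, 9), (10, 14), (15, 19))  # plus the open ">19" bin
UNIT_CLASS_NAMES = {2: "dinucleotide", 3: "trinucleotide",
                    4: "tetranucleotide", 5: "pentanucleotide"}


def canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_degenerate_unit(unit: str) -> bool:
    """Mononucleotide-periodic or otherwise self-periodic seed units."""
    if "N" in unit:
        return True
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return True
    return False


def scan(sequence: str, contig_id: str = "", unit_lengths=UNIT_LENGTHS,
         mismatch_penalty: int = MISMATCH_PENALTY, match_score: int = MATCH_SCORE,
         min_score: int = MIN_SCORE, min_units: int = MIN_UNITS) -> list[RepeatHit]:
    """All deduplicated repeat loci in ``sequence`` (1-based coordinates)."""
    seq = sequence.upper()
    n = len(seq)
    candidates: list[RepeatHit] = []
    for k in unit_lengths:
        i = 0
        while i + k <= n:
            unit = seq[i:i + k]
            if _is_degenerate_unit(unit):
                i += 1
                continue
            score = 0
            best_score, best_end, mism, best_mism = 0, i + k - 1, 0, 0
            j = i + k
            while j < n:
                if seq[j] == unit[(j - i) % k] and seq[j] != "N":
                    score += match_score
                else:
                    score += mismatch_penalty
                    mism += 1
                if score < 0:
                    break
                if score > best_score:
                    best_score, best_end, best_mism = score, j, mism
                j += 1
            span = best_end - i + 1
            n_units = span // k
            if best_score >= min_score and n_units >= min_units:
                candidates.append(RepeatHit(
                    contig_id=contig_id, start=i + 1, end=best_end + 1,
                    unit=canonical_rotation(unit), n_units=n_units,
                    score=best_score, mismatches=best_mism))
            i += 1
    return _deduplicate(candidates)


def _deduplicate(candidates: list[RepeatHit]) -> list[RepeatHit]:
    """Greedy overlap removal: highest score, then longest, then smallest k."""
    ranked = sorted(candidates,
                    key=lambda h: (-h.score, -(h.end - h.start + 1),
                                   len(h.unit), h.start))
    kept: list[RepeatHit] = []
    for hit in ranked:
        if all(hit.end < other.start or hit.start > other.end for other in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def scan_contigs(contigs, **kwargs) -> list[RepeatHit]:
    hits: list[RepeatHit] = []
    for c in contigs:
        hits.extend(scan(c.sequence, contig_id=c.id, **kwargs))
    return hits


def hits_frame(hits: list[RepeatHit]) -> pd.DataFrame:
    return pd.DataFrame({
        "contig_id": [h.contig_id for h in hits],
        "start": [h.start for h in hits],
        "end": [h.end for h in hits],
        "unit": [h.unit for h in hits],
        "unit_length": [len(h.unit) for h in hits],
        "n_units": [h.n_units for h in hits],
        "score": [h.score for h in hits],
        "mismatches": [h.mismatches for h in hits],
    })


def bin_repeats(hits: list[RepeatHit]) -> pd.DataFrame:
    """Unit-length class x repeat-count bins (5-9, 10-14, 15-19, >19)."""
    unit_lengths = [len(h.unit) for h in hits]
    n_units = [h.n_units for h in hits]
    return bin_repeat_counts(unit_lengths, n_units)


def bin_repeat_counts(unit_lengths, n_units) -> pd.DataFrame:
    rows = []
    for k in UNIT_LENGTHS:
        units_k = [n for ul, n in zip(unit_lengths, n_units) if ul == k]
        row = {"repeat_type": UNIT_CLASS_NAMES[k]}
        for lo, hi in REPEAT_BINS:
            row[f"{lo}-{hi}"] = sum(1 for n in units_k if lo <= n <= hi)
        row[">19"] = sum(1 for n in units_k if n > 19)
        row["max_units"] = max(units_k, default=0)
        row["total"] = len(units_k)
        rows.append(row)
    frame = pd.DataFrame(rows)
    totals = {"repeat_type": "all"}
    for col in frame.columns[1:]:
        totals[col] = int(frame[col].max()) if col == "max_units" else int(frame[col].sum())
    return pd.concat([frame, pd.DataFrame([totals])], ignore_index=True)


def totalise_repeat_table(table: pd.DataFrame) -> dict:
    """Row/grand totals of a binned repeat table (bins + per-type totals)."""
    bins = [f"{lo}-{hi}" for lo, hi in REPEAT_BINS] + [">19"]
    body = table[table["repeat_type"] != "all"]
    row_totals = {
        row["repeat_type"]: int(sum(row[b] for b in bins))
        for _, row in body.iterrows()
    }
    return {"row_totals": row_totals, "grand_total": int(sum(row_totals.values()))}


def extract_flanks(sequence: str, hit: RepeatHit, flank: int = 100,
                   min_flank: int = 10, max_total_flank: int = 200) -> dict:
    """Repeat tract with up to ``flank`` bases either side.

    Flanks are truncated at contig ends; records with fewer than
    ``min_flank`` bases on either side are flagged.  Total flank never
    exceeds ``max_total_flank`` (two full flanks at the defaults).
    """
    if hit.start < 1 or hit.end > len(sequence):
        raise ValueError("hit outside sequence")
    per_side = min(flank, max_total_flank // 2)
    left = sequence[max(0, hit.start - 1 - per_side):hit.start - 1]
    right = sequence[hit.end:hit.end + per_side]
    return {
        "contig_id": hit.contig_id,
        "left_flank": left,
        "repeat": sequence[hit.start - 1:hit.end],
        "right_flank": right,
        "short_flank": min(len(left), len(right)) < min_flank,
    }
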