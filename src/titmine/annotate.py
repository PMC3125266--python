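"""Positional annotation of contig alignments against gene models.

Each contig interval is related to its nearest gene and assigned one of six
classes: A (contig strictly downstream of the gene, i.e. at higher genomic
coordinates), B (strictly upstream), C (downstream but overlapping the gene's
end), D (upstream but overlapping the gene's start), E (contig spans the whole
gene), F (gene spans the whole contig).  Upstream/downstream are genomic
coordinate notions, never strand-relative; feature ordinals ("first exon",
"final intron") are strand-relative transcript order.

Distance is the count of bases strictly between the two intervals — zero on
any overlap, and zero for intervals that touch with no intervening base.

A random-placement null is provided: contig lengths are resampled, dropped
uniformly onto length-weighted chromosomes, and the nearest-gene distance
recorded; the observed and simulated distance distributions are compared with
a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np
import pandas as pd
from scipy import stats

from .models import ContigAlignment, Gene, GenomeAnnotation, PositionalCall

PROXIMITY_THRESHOLDS = (2500, 5000, 7500, 10000)
DEFAULT_NULL_REPLICATES = 1_000_000
DEFAULT_BIN = 500_000


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Bases strictly between two closed intervals; 0 on overlap or touch."""
    if a_start > b_end:
        return a_start - b_end - 1
    if b_start > a_end:
        return b_start - a_end - 1
    return 0


def nearest_gene(contig: ContigAlignment, genome: GenomeAnnotation
                 ) -> tuple[Gene | None, int | None]:
    """Nearest gene on the contig's chromosome and the intervening distance.

    Ties are broken by lower gene start, then gene id.  Returns
    ``(None, None)`` on a chromosome with no annotated genes.
    """
    if contig.chromosome not in genome.chromosomes:
        raise ValueError(f"contig on unannotated chromosome {contig.chromosome}")
    genes = genome.genes_on(contig.chromosome)
    if not genes:
        return None, None
    best: Gene | None = None
    best_d = None
    for g in genes:
        d = interval_distance(contig.start, contig.end, g.start, g.end)
        if best_d is None or d < best_d or (
                d == best_d and (g.start, g.id) < (best.start, best.id)):
            best, best_d = g, d
    return best, best_d


def _feature_at(gene: Gene, pos: int) -> tuple[str, int] | None:
    for f in gene.features:
        if f.start <= pos <= f.end:
            return (f.type, f.ordinal)
    return None


def classify_contig(contig: ContigAlignment, gene: Gene,
                    genome: GenomeAnnotation | None = None) -> PositionalCall:
    """Assign the contig's positional class relative to ``gene``.

    For overlap classes the contig's genomic-left (``start_feature``) and
    genomic-right (``end_feature``) ends are located within the gene's feature
    structure when they fall inside the gene span.
    """
    s, e = contig.start, contig.end
    d = interval_distance(s, e, gene.start, gene.end)
    if d > 0 or (d == 0 and (s > gene.end or e < gene.start)):
        klass = "A" if s > gene.end else "B"
        return PositionalCall(contig_id=contig.contig_id,
                              nearest_gene_id=gene.id, distance=d, klass=klass)
    if s <= gene.start and e >= gene.end:
        klass = "E"
    elif s >= gene.start and e <= gene.end:
        klass = "F"
    elif e > gene.end:
        klass = "C"  # overlaps the gene's downstream (right) end
    else:
        klass = "D"  # overlaps the gene's upstream (left) end
    start_feature = _feature_at(gene, s) if s >= gene.start else None
    end_feature = _feature_at(gene, e) if e <= gene.end else None
    return PositionalCall(contig_id=contig.contig_id, nearest_gene_id=gene.id,
                          distance=0, klass=klass,
                          start_feature=start_feature, end_feature=end_feature)


def annotate(alignments: list[ContigAlignment], genome: GenomeAnnotation
             ) -> list[PositionalCall]:
    calls = []
    for aln in alignments:
        gene, d = nearest_gene(aln, genome)
        if gene is None:
            calls.append(PositionalCall(contig_id=aln.contig_id,
                                        nearest_gene_id=None, distance=None,
                                        klass=None))
        else:
            calls.append(classify_contig(aln, gene))
    return calls


def calls_frame(calls: list[PositionalCall]) -> pd.DataFrame:
    def fmt(feat):
        return "" if feat is None else f"{feat[0]}:{feat[1]}"

    return pd.DataFrame({
        "contig_id": [c.contig_id for c in calls],
        "nearest_gene_id": [c.nearest_gene_id or "" for c in calls],
        "distance": [c.distance if c.distance is not None else np.nan for c in calls],
        "class": [c.klass or "" for c in calls],
        "start_feature": [fmt(c.start_feature) for c in calls],
        "end_feature": [fmt(c.end_feature) for c in calls],
    })


# ---------------------------------------------------------------------------
# Random-placement null


class _ChromIndex:
    """Sorted non-overlapping gene spans for fast nearest-distance queries."""

    def __init__(self, genes: list[Gene]):
        spans = sorted((g.start, g.end) for g in genes)
        self.starts = np.array([s for s, _ in spans], dtype=np.int64)
        self.ends = np.array([e for _, e in spans], dtype=np.int64)

    def distances(self, s: np.ndarray, e: np.ndarray) -> np.ndarray:
        if len(self.starts) == 0:
            return np.full(len(s), -1, dtype=np.int64)
        j = np.searchsorted(self.starts, e, side="right")  # genes starting after e
        left = np.full(len(s), np.iinfo(np.int64).max, dtype=np.int64)
        has_left = j > 0
        le = self.ends[np.maximum(j - 1, 0)]
        left[has_left] = np.maximum(s[has_left] - le[has_left] - 1, 0)
        right = np.full(len(s), np.iinfo(np.int64).max, dtype=np.int64)
        has_right = j < len(self.starts)
        rs = self.starts[np.minimum(j, len(self.starts) - 1)]
        right[has_right] = np.maximum(rs[has_right] - e[has_right] - 1, 0)
        return np.minimum(left, right)


def simulate_null_distances(contig_lengths, genome: GenomeAnnotation,
                            n_replicates: int = DEFAULT_NULL_REPLICATES,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Nearest-gene distances of randomly placed contigs.

    Per replicate: a contig length is drawn uniformly from ``contig_lengths``,
    a chromosome with probability proportional to its length among those the
    contig fits on, and a start position uniform over the fitting range.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.asarray(contig_lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no contig lengths supplied")
    chroms = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chroms], dtype=np.int64)
    if lengths.min() > chrom_lens.max():
        raise ValueError("every contig is longer than every chromosome")
    indexes = {c: _ChromIndex(genome.genes_on(c)) for c in chroms}

    drawn = lengths[rng.integers(0, lengths.size, size=n_replicates)]
    out = np.empty(n_replicates, dtype=np.int64)
    # group replicates by distinct contig length so chromosome weights (which
    # depend on which chromosomes the contig fits) stay exact
    order = np.argsort(drawn, kind="stable")
    drawn_sorted = drawn[order]
    boundaries = np.flatnonzero(np.diff(drawn_sorted)) + 1
    groups = np.split(np.arange(n_replicates)[order], boundaries)
    for grp in groups:
        L = int(drawn[grp[0]])
        fits = chrom_lens >= L
        if not fits.any():
            raise ValueError(f"contig of {L} bp does not fit on any chromosome")
        p = np.where(fits, chrom_lens, 0).astype(float)
        p /= p.sum()
        chosen = rng.choice(len(chroms), size=len(grp), p=p)
        starts = np.empty(len(grp), dtype=np.int64)
        for ci in np.unique(chosen):
            mask = chosen == ci
            hi = chrom_lens[ci] - L + 1
            starts[mask] = rng.integers(1, hi + 1, size=mask.sum())
        ends = starts + L - 1
        dists = np.empty(len(grp), dtype=np.int64)
        for ci in np.unique(chosen):
            mask = chosen == ci
            d = indexes[chroms[ci]].distances(starts[mask], ends[mask])
            dists[mask] = d
        out[grp] = dists
    if (out < 0).any():
        # chromosomes without genes yield no defined distance
        out = out[out >= 0]
    return out


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_a - ECDF_b| with asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Summaries


def binned_density(alignments: list[ContigAlignment], genome: GenomeAnnotation,
                   bin_size: int = DEFAULT_BIN,
                   weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-chromosome binned counts of alignment start positions.

    Bins are left-closed right-open, anchored at coordinate 1; an optional
    per-contig weight (e.g. read depth) turns counts into summed depth.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    rows = []
    per_chrom: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes.items():
        per_chrom[chrom] = np.zeros((length - 1) // bin_size + 1)
    for aln in alignments:
        w = 1.0 if weights is None else float(weights.get(aln.contig_id, 0.0))
        per_chrom[aln.chromosome][(aln.start - 1) // bin_size] += w
    for chrom, counts in per_chrom.items():
        for i, c in enumerate(counts):
            rows.append({"chromosome": chrom, "bin_start": i * bin_size + 1,
                         "bin_end": min((i + 1) * bin_size, genome.chromosomes[chrom]),
                         "count": c})
    return pd.DataFrame(rows)


def proximity_table(calls: list[PositionalCall],
                    thresholds=PROXIMITY_THRESHOLDS) -> pd.DataFrame:
    """Cumulative distance-to-nearest-gene counts for flanking classes A/B."""
    rows = []
    for klass in ("A", "B"):
        ds = [c.distance for c in calls if c.klass == klass and c.distance is not None]
        row = {"class": klass, "total": len(ds)}
        for t in thresholds:
            row[f"<{t}"] = sum(1 for d in ds if d < t)
        rows.append(row)
    return pd.DataFrame(rows)


def proximal_fraction(counts_within, totals) -> float:
    """Share of flanking contigs within a distance bin, from table counts."""
    total = float(np.sum(totals))
    if total == 0:
        raise ValueError("no flanking contigs")
    return float(np.sum(counts_within)) / total
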