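"""Core in-memory containers shared across the mining stages.

Coordinate convention: 1-based, fully closed intervals everywhere (Ensembl
style).  A feature ``(start, end)`` covers ``end - start + 1`` bases; adjacent
features of a gene satisfy ``next.start == prev.end + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_TYPES = ("five_prime_UTR", "exon", "intron", "three_prime_UTR")


@dataclass(frozen=True)
class Feature:
    """One gene feature in genomic coordinates.

    ``ordinal`` counts in transcript (strand) order: exon 1 is the first exon
    read 5'->3' on the coding strand, so for a minus-strand gene it is the
    right-most exon in genomic coordinates.
    """

    type: str
    start: int
    end: int
    ordinal: int

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.start > self.end:
            raise ValueError("feature start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Gene:
    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        # features must tile the span exactly, in genomic order, no gaps
        feats = sorted(self.features, key=lambda f: f.start)
        if feats:
            if feats[0].start != self.start or feats[-1].end != self.end:
                raise ValueError(f"gene {self.id}: features do not tile span")
            for a, b in zip(feats, feats[1:]):
                if b.start != a.end + 1:
                    raise ValueError(f"gene {self.id}: gap/overlap between features")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def n_features(self, ftype: str) -> int:
        return sum(1 for f in self.features if f.type == ftype)


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus gene models with tiled feature structure."""

    chromosomes: dict[str, int]
    genes: list[Gene]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chromosome not in self.chromosomes:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chromosome}")
            if g.end > self.chromosomes[g.chromosome]:
                raise ValueError(f"gene {g.id} extends past chromosome end")

    def genes_on(self, chromosome: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes if g.chromosome == chromosome),
            key=lambda g: (g.start, g.id),
        )


@dataclass(frozen=True)
class ContigRecord:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ContigAlignment:
    """Placement of a contig on a chromosome (best genome hit)."""

    contig_id: str
    chromosome: str
    start: int
    end: int
    percent_identity: float = 100.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("alignment start > end")


@dataclass
class ExpressionMatrix:
    """Contig x tissue read counts with per-tissue library sizes.

    ``counts`` is a DataFrame indexed by contig id with one column per tissue;
    ``library_sizes`` a Series over the same tissues (total reads per library).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if self.counts.shape[1] < 2:
            raise ValueError("need at least two tissues")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValueError("every tissue needs a positive library size")

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def contigs(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class TauResult:
    contig_id: str
    tau: float | None  # None for contigs absent from every tissue
    tpm: tuple[float, ...]
    tpm_max: float
    breadth: str  # "ubiquitous" | "tissue_specific:<tissue>" | "intermediate" | "absent"


@dataclass(frozen=True)
class PositionalCall:
    """Relation of a contig alignment to its nearest gene (classes A-F).

    Classes: A contig downstream (higher coordinates) of the gene; B upstream;
    C downstream overlapping the gene end; D upstream overlapping the gene
    start; E contig spans the gene; F gene spans the contig.  ``distance`` is
    the count of bases strictly between the two intervals (0 on any overlap).
    ``start_feature``/``end_feature`` are ``(type, ordinal)`` of the feature
    containing the contig's left/right genomic end, when that end lies inside
    the gene.
    """

    contig_id: str
    nearest_gene_id: str | None
    distance: int | None
    klass: str | None
    start_feature: tuple[str, int] | None = None
    end_feature: tuple[str, int] | None = None


@dataclass(frozen=True)
class RepeatHit:
    """A scored microsatellite locus (1-based closed interval)."""

    contig_id: str
    start: int
    end: int
    unit: str
    n_units: int
    score: int
    mismatches: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1
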