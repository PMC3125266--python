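"""Synthetic inputs with the statistical structure the mining stages assume.

The generator emulates a normalised multi-tissue cDNA sequencing study: a small
genome with tiled gene models, a contig set drawn from a tunable mixture of
mRNA / pre-mRNA / intergenic placements, tissue-resolved read counts with a
controllable tissue-specific fraction, SNP candidate tables with planted true
sites and rule-violating artifacts, planted microsatellites, and a miniature GO
DAG with a gene->term map.  Every synthetic entity carries a ground-truth label
so downstream classifiers can be scored exactly.

All randomness flows through one ``numpy.random.Generator``; identical seed and
config yield byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    ContigAlignment,
    ContigRecord,
    Feature,
    Gene,
    GenomeAnnotation,
)

CONTIG_CLASSES = ("mRNA", "pre_mRNA", "intergenic_near", "intergenic_far")
GO_ROOTS = {
    "GO:0008150": "biological_process",
    "GO:0003674": "molecular_function",
    "GO:0005575": "cellular_component",
}
_BASES = np.array(list("ACGT"))


class FeasibilityError(ValueError):
    """Raised when the requested genes cannot fit on the chromosomes."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the structure of an eight-tissue normalised cDNA study:
    21% of contigs single-tissue, a minimum of four reads defining tissue
    specificity, and a contig mixture weighted towards mRNA and pre-mRNA
    (roughly a third of contigs matching known transcripts, with most of the
    remainder inside or near genes).
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_lengths: list[int] | None = None
    n_genes: int = 80
    exons_per_gene_range: tuple[int, int] = (1, 6)
    feature_length_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "five_prime_UTR": (50, 200),
        "exon": (80, 300),
        "intron": (200, 1500),
        "three_prime_UTR": (50, 300),
    })
    n_contigs: int = 400
    contig_length_range: tuple[int, int] = (200, 1500)
    class_mixture: dict[str, float] = field(default_factory=lambda: {
        "mRNA": 0.35, "pre_mRNA": 0.35,
        "intergenic_near": 0.20, "intergenic_far": 0.10,
    })
    near_distance: int = 5000  # max gap for "intergenic-near" placement
    n_tissues: int = 8
    library_size_range: tuple[int, int] = (200_000, 600_000)
    prop_tissue_specific: float = 0.21
    min_specific_reads: int = 4
    mean_total_reads: float = 60.0
    expression_dispersion: float = 0.7  # gamma shape of the count mixing dist
    snp_true_rate: float = 1.0     # per kb of contig sequence
    snp_artifact_rate: float = 2.0  # per kb
    planted_repeats: list[tuple[str, int, int]] = field(default_factory=lambda: [
        ("AC", 8, 0), ("AAG", 7, 0), ("AGAT", 6, 1),
    ])
    go_terms_per_namespace: int = 15
    prop_genes_annotated: float = 0.74

    def __post_init__(self) -> None:
        if self.chromosome_lengths is None:
            base = [400_000, 300_000, 200_000, 100_000]
            self.chromosome_lengths = [
                base[i % 4] for i in range(self.n_chromosomes)
            ]
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must have n_chromosomes entries")
        for name in ("n_chromosomes", "n_genes", "n_contigs", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be strictly positive")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture sums to {total}, expected 1")
        for k in self.class_mixture:
            if k not in CONTIG_CLASSES:
                raise ValueError(f"unknown contig class {k!r}")
        if not 0.0 <= self.prop_tissue_specific <= 1.0:
            raise ValueError("prop_tissue_specific must be in [0, 1]")
        if self.snp_true_rate < 0 or self.snp_artifact_rate < 0:
            raise ValueError("SNP rates must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    """Ground-truth labels for everything the generator planted."""

    contig_classes: pd.DataFrame   # contig_id, label, gene_id, chromosome, start, end
    planted_repeats: pd.DataFrame  # contig_id, unit, n_units, n_mismatches, position


# ---------------------------------------------------------------------------
# Genome


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _draw_gene_structure(rng: np.random.Generator, config: SimulationConfig):
    """Transcript-order feature (type, length) list for one gene."""
    r = config.feature_length_ranges
    lo, hi = config.exons_per_gene_range
    n_exons = int(rng.integers(lo, hi + 1))
    feats = [("five_prime_UTR", int(rng.integers(*r["five_prime_UTR"])) )]
    for i in range(n_exons):
        feats.append(("exon", int(rng.integers(*r["exon"]))))
        if i < n_exons - 1:
            feats.append(("intron", int(rng.integers(*r["intron"]))))
    feats.append(("three_prime_UTR", int(rng.integers(*r["three_prime_UTR"]))))
    return feats


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenomeAnnotation:
    """Place non-overlapping genes whose features tile their spans exactly."""
    rng = config.rng() if rng is None else rng
    structures = [_draw_gene_structure(rng, config) for _ in range(config.n_genes)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(config.n_genes)]
    lengths = [sum(l for _, l in s) for s in structures]

    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    total_len = {c: l for c, l in zip(chrom_ids, config.chromosome_lengths)}
    remaining = dict(total_len)
    assignment: dict[str, list[int]] = {c: [] for c in chrom_ids}
    for gi in range(config.n_genes):
        # highest free *fraction* first: genes spread across all chromosomes
        # roughly in proportion to length, so none stays gene-free
        best = max(chrom_ids, key=lambda c: remaining[c] / total_len[c])
        need = lengths[gi] + 1  # at least 1 bp gap to the neighbour
        if remaining[best] < need:
            best = max(chrom_ids, key=lambda c: remaining[c])
        if remaining[best] < need:
            raise FeasibilityError(
                f"cannot fit gene of {lengths[gi]} bp: largest free space "
                f"{remaining[best]} bp"
            )
        assignment[best].append(gi)
        remaining[best] -= need

    genes: list[Gene] = []
    for ci, chrom in enumerate(chrom_ids):
        idxs = assignment[chrom]
        if not idxs:
            continue
        chrom_len = config.chromosome_lengths[ci]
        total = sum(lengths[i] for i in idxs)
        n = len(idxs)
        # n+1 gap slots; the n-1 interior gaps get at least 1 bp
        spare = chrom_len - total - (n - 1)
        gaps = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1)))
        pos = 1
        for slot, gi in enumerate(idxs):
            pos += int(gaps[slot]) + (1 if slot > 0 else 0)
            start = pos
            struct = structures[gi]
            genomic = struct if strands[gi] == "+" else list(reversed(struct))
            counters = {t: 0 for t in ("exon", "intron")}
            n_of = {t: sum(1 for ft, _ in struct if ft == t) for t in ("exon", "intron")}
            feats = []
            cur = start
            for ftype, flen in genomic:
                if ftype in counters:
                    counters[ftype] += 1
                    # ordinal in transcript order
                    if strands[gi] == "+":
                        ordinal = counters[ftype]
                    else:
                        ordinal = n_of[ftype] - counters[ftype] + 1
                else:
                    ordinal = 1
                feats.append(Feature(type=ftype, start=cur, end=cur + flen - 1,
                                     ordinal=ordinal))
                cur += flen
            end = cur - 1
            genes.append(Gene(id=f"gene{gi + 1:04d}", chromosome=chrom,
                              strand=strands[gi], start=start, end=end,
                              features=tuple(feats)))
            pos = end + 1
    genes.sort(key=lambda g: (g.chromosome, g.start, g.id))
    return GenomeAnnotation(
        chromosomes=dict(zip(chrom_ids, config.chromosome_lengths)), genes=genes
    )


def generate_genome_sequences(genome: GenomeAnnotation,
                              rng: np.random.Generator) -> dict[str, str]:
    return {c: _random_sequence(rng, l) for c, l in genome.chromosomes.items()}


# ---------------------------------------------------------------------------
# Contigs


def _gene_intervals(genome: GenomeAnnotation) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    for g in genome.genes:
        by_chrom[g.chromosome].append((g.start, g.end))
    for c in by_chrom:
        by_chrom[c].sort()
    return by_chrom


def _overlaps_any(intervals: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(a <= e and b >= s for a, b in intervals)


def generate_contigs(
    genome: GenomeAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sequences: dict[str, str] | None = None,
) -> tuple[list[ContigRecord], list[ContigAlignment], SyntheticTruth]:
    """Draw contigs from the configured mRNA/pre-mRNA/intergenic mixture.

    mRNA contigs carry spliced exon sequence of one gene; pre-mRNA contigs are
    windows inside a single intron (the dominant pattern for unspliced
    precursor contigs); intergenic-near contigs sit within ``near_distance``
    of a gene without touching it; intergenic-far contigs are uniform
    placements that avoid gene spans.
    """
    if not genome.genes:
        raise ValueError("genome has no genes")
    rng = config.rng() if rng is None else rng
    if sequences is None:
        sequences = generate_genome_sequences(genome, rng)
    chrom_ids = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_ids], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    genic = _gene_intervals(genome)
    intron_genes = [g for g in genome.genes if g.n_features("intron") > 0]

    labels = list(config.class_mixture)
    probs = np.array([config.class_mixture[k] for k in labels])
    draw = rng.choice(len(labels), size=config.n_contigs, p=probs)

    contigs: list[ContigRecord] = []
    alignments: list[ContigAlignment] = []
    rows = []
    for i in range(config.n_contigs):
        label = labels[draw[i]]
        length = int(rng.integers(config.contig_length_range[0],
                                  config.contig_length_range[1] + 1))
        cid = f"contig{i + 1:05d}"
        if label == "mRNA":
            gene = genome.genes[int(rng.integers(len(genome.genes)))]
            exons = sorted((f for f in gene.features if f.type == "exon"),
                           key=lambda f: f.start)
            spliced = "".join(sequences[gene.chromosome][f.start - 1:f.end] for f in exons)
            if len(spliced) > length:
                off = int(rng.integers(0, len(spliced) - length + 1))
                seq = spliced[off:off + length]
            else:
                seq = spliced
            s, e = exons[0].start, exons[-1].end
            gid, chrom = gene.id, gene.chromosome
        elif label == "pre_mRNA":
            if not intron_genes:
                raise ValueError("pre_mRNA contigs requested but no gene has introns")
            gene = intron_genes[int(rng.integers(len(intron_genes)))]
            introns = [f for f in gene.features if f.type == "intron"]
            intron = introns[int(rng.integers(len(introns)))]
            win = min(length, intron.length)
            s = int(rng.integers(intron.start, intron.end - win + 2))
            e = s + win - 1
            seq = sequences[gene.chromosome][s - 1:e]
            gid, chrom = gene.id, gene.chromosome
        elif label == "intergenic_near":
            gene, s, e = _place_near(genome, genic, rng, length, config.near_distance)
            seq = sequences[gene.chromosome][s - 1:e]
            gid, chrom = gene.id, gene.chromosome
        else:  # intergenic_far: uniform placement avoiding gene spans
            for _ in range(10_000):
                ci = int(rng.choice(len(chrom_ids), p=chrom_p))
                chrom = chrom_ids[ci]
                L = genome.chromosomes[chrom]
                win = min(length, L)
                s = int(rng.integers(1, L - win + 2))
                e = s + win - 1
                if not _overlaps_any(genic[chrom], s, e):
                    break
            else:
                raise RuntimeError("could not place intergenic-far contig")
            seq = sequences[chrom][s - 1:e]
            gid = ""
        contigs.append(ContigRecord(id=cid, sequence=seq))
        alignments.append(ContigAlignment(contig_id=cid, chromosome=chrom,
                                          start=s, end=e,
                                          percent_identity=100.0, e_value=0.0))
        rows.append({"contig_id": cid, "label": label, "gene_id": gid,
                     "chromosome": chrom, "start": s, "end": e})

    truth = pd.DataFrame(rows, columns=["contig_id", "label", "gene_id",
                                        "chromosome", "start", "end"])
    contigs, repeats = _plant_configured_repeats(contigs, config, rng)
    return contigs, alignments, SyntheticTruth(contig_classes=truth,
                                               planted_repeats=repeats)


def _place_near(genome: GenomeAnnotation, genic, rng, length: int, near: int):
    """Pick (gene, start, end) outside every gene but within ``near`` bp of one."""
    genes = genome.genes
    for _ in range(10_000):
        gene = genes[int(rng.integers(len(genes)))]
        L = genome.chromosomes[gene.chromosome]
        gap = int(rng.integers(10, near + 1))
        if rng.random() < 0.5:  # downstream of the gene (higher coordinates)
            s = gene.end + 1 + gap
            e = s + length - 1
        else:
            e = gene.start - 1 - gap
            s = e - length + 1
        if s < 1 or e > L:
            continue
        if not _overlaps_any(genic[gene.chromosome], s, e):
            return gene, s, e
    raise RuntimeError("could not place intergenic-near contig")


# ---------------------------------------------------------------------------
# Microsatellite planting


def _validate_repeat_unit(unit: str) -> None:
    unit = unit.upper()
    if not 2 <= len(unit) <= 5 or any(b not in "ACGT" for b in unit):
        raise ValueError(f"repeat unit must be 2-5 bp over ACGT, got {unit!r}")
    # reject self-periodic units ("ATAT" -> period 2, "AA" -> mononucleotide)
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            raise ValueError(f"repeat unit {unit!r} is self-periodic (period {p})")


def plant_repeats(sequence: str, spec: tuple[str, int, int], position: int) -> str:
    """Overwrite a window of ``sequence`` with a (possibly imperfect) repeat.

    ``spec`` is ``(unit, n_units, n_mismatches)``; ``position`` is 1-based.
    Mismatched bases are substituted at evenly spaced interior unit cells
    (never the first unit), each replaced by the next base cyclically.
    """
    unit, n_units, n_mismatches = spec
    unit = unit.upper()
    _validate_repeat_unit(unit)
    tract = list(unit * n_units)
    if n_mismatches:
        if n_units < 3:
            raise ValueError("need >= 3 units to plant interior mismatches")
        k = len(unit)
        for j in range(n_mismatches):
            # spread over interior units, clear of both tract ends
            cell = 1 + ((j + 1) * (n_units - 2)) // (n_mismatches + 1)
            idx = cell * k + k // 2
            order = "ACGT"
            tract[idx] = order[(order.index(tract[idx]) + 1) % 4]
    tract_s = "".join(tract)
    if position < 1 or position + len(tract_s) - 1 > len(sequence):
        raise ValueError("planted repeat does not fit in the sequence")
    i = position - 1
    return sequence[:i] + tract_s + sequence[i + len(tract_s):]


def _plant_configured_repeats(contigs: list[ContigRecord], config: SimulationConfig,
                              rng: np.random.Generator):
    rows = []
    contigs = list(contigs)
    if not config.planted_repeats:
        return contigs, pd.DataFrame(
            columns=["contig_id", "unit", "n_units", "n_mismatches", "position"])
    eligible = [i for i, c in enumerate(contigs)
                if c.length >= max(len(u) * n + 20 for u, n, _ in config.planted_repeats)]
    for j, spec in enumerate(config.planted_repeats):
        if not eligible:
            break
        i = eligible[j % len(eligible)]
        c = contigs[i]
        tract_len = len(spec[0]) * spec[1]
        pos = int(rng.integers(11, c.length - tract_len - 9))
        contigs[i] = ContigRecord(id=c.id, sequence=plant_repeats(c.sequence, spec, pos))
        rows.append({"contig_id": c.id, "unit": spec[0], "n_units": spec[1],
                     "n_mismatches": spec[2], "position": pos})
    return contigs, pd.DataFrame(rows, columns=["contig_id", "unit", "n_units",
                                                "n_mismatches", "position"])


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    contigs: Sequence[ContigRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Tissue-resolved read counts: a tissue-specific fraction gets >= 4 reads
    in exactly one tissue, the remainder multinomial counts across tissues.

    Returns ``(ExpressionMatrix, truth)`` where truth records the planted
    breadth of every contig.
    """
    from .models import ExpressionMatrix

    if config.n_tissues < 2:
        raise ValueError("need at least two tissues")
    rng = config.rng() if rng is None else rng
    tissues = [f"tissue{t + 1}" for t in range(config.n_tissues)]
    n = len(contigs)
    counts = np.zeros((n, config.n_tissues), dtype=np.int64)
    specific = rng.random(n) < config.prop_tissue_specific
    truth_rows = []
    for i in range(n):
        if specific[i]:
            t = int(rng.integers(config.n_tissues))
            counts[i, t] = config.min_specific_reads + rng.poisson(
                max(config.mean_total_reads / 2 - config.min_specific_reads, 1.0))
            truth_rows.append({"contig_id": contigs[i].id,
                               "truth_breadth": f"tissue_specific:{tissues[t]}"})
        else:
            mean = rng.gamma(config.expression_dispersion,
                             config.mean_total_reads / config.expression_dispersion)
            total = int(rng.poisson(mean)) + 1
            counts[i] = rng.multinomial(total, np.full(config.n_tissues,
                                                       1.0 / config.n_tissues))
            truth_rows.append({"contig_id": contigs[i].id,
                               "truth_breadth": "multinomial"})
    frame = pd.DataFrame(counts, index=[c.id for c in contigs], columns=tissues)
    frame.index.name = "contig_id"
    col_sums = frame.sum(axis=0)
    drawn = rng.integers(config.library_size_range[0],
                         config.library_size_range[1] + 1, size=config.n_tissues)
    libs = pd.Series(np.maximum(drawn, col_sums.to_numpy()), index=tissues)
    return ExpressionMatrix(counts=frame, library_sizes=libs), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# SNP candidates


_ARTIFACT_KINDS = ("low_quality", "low_neighbour", "indel", "low_depth",
                   "low_maf", "low_minor", "near_end", "clustered")


def _true_snp_row(rng: np.random.Generator) -> dict:
    depth = 8 + int(rng.poisson(20))
    if depth <= 20:
        lo = max(3, math.ceil(0.25 * depth))
    else:
        lo = 3
    minor = int(np.clip(rng.binomial(depth, 0.35), lo, depth // 2))
    ref, alt = rng.choice(4, size=2, replace=False)
    return {"ref_allele": "ACGT"[ref], "alt_allele": "ACGT"[alt],
            "depth": depth, "minor_count": minor,
            "snp_quality": 31 + int(rng.integers(0, 15)),
            "min_neighbour_quality": 21 + int(rng.integers(0, 20)),
            "is_indel": False}


def generate_snp_candidates(
    contigs: Sequence[ContigRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """SNP candidate table with truth labels.

    True SNPs are placed >= 60 bp apart and >= 50 bp from contig ends with
    depth/allele/quality values that survive the modest-stringency cascade;
    artifacts each violate one cascade rule while remaining isolated enough
    not to disturb the true sites.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    rng = config.rng() if rng is None else rng
    rows: list[dict] = []
    margin, spacing = 50, 60
    for c in contigs:
        L = c.length
        slots = np.arange(margin + 1, L - margin, spacing)
        if len(slots) == 0:
            continue
        rng.shuffle(slots)
        slots = list(slots)
        n_true = int(rng.poisson(config.snp_true_rate * L / 1000))
        n_art = int(rng.poisson(config.snp_artifact_rate * L / 1000))
        for _ in range(min(n_true, len(slots))):
            pos = int(slots.pop())
            row = _true_snp_row(rng)
            row.update({"contig_id": c.id, "position": pos, "is_true": True})
            rows.append(row)
        end_used = 0
        for _ in range(n_art):
            kind = _ARTIFACT_KINDS[int(rng.integers(len(_ARTIFACT_KINDS)))]
            if kind == "near_end" and end_used < 2 and L > 120:
                pos = int(rng.integers(1, 12)) if end_used == 0 else L - int(rng.integers(0, 11))
                end_used += 1
                row = _true_snp_row(rng)
                row.update({"contig_id": c.id, "position": pos, "is_true": False})
                rows.append(row)
                continue
            if not slots:
                break
            pos = int(slots.pop())
            if kind == "clustered":
                for p in (pos, pos + 10):
                    row = _true_snp_row(rng)
                    row.update({"contig_id": c.id, "position": p, "is_true": False})
                    rows.append(row)
                continue
            row = _true_snp_row(rng)
            if kind == "low_quality":
                row["snp_quality"] = int(rng.integers(5, 31))
            elif kind == "low_neighbour":
                row["min_neighbour_quality"] = int(rng.integers(0, 21))
            elif kind == "indel":
                row["is_indel"] = True
                row["alt_allele"] = "-"
            elif kind == "low_depth":
                d = int(rng.integers(2, 8))
                row["depth"], row["minor_count"] = d, max(1, d // 3)
            elif kind == "low_maf":
                d = int(rng.integers(8, 21))
                row["depth"], row["minor_count"] = d, max(1, int(0.24 * d))
            elif kind == "low_minor":
                row["depth"], row["minor_count"] = 21 + int(rng.poisson(20)), 2
            row.update({"contig_id": c.id, "position": pos, "is_true": False})
            rows.append(row)
    columns = ["contig_id", "position", "ref_allele", "alt_allele", "depth",
               "minor_count", "snp_quality", "min_neighbour_quality",
               "is_indel", "is_true"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(["contig_id", "position"]).reset_index(drop=True)


def plant_snp_string(candidates: pd.DataFrame, contig_id: str, start: int,
                     n_snps: int = 6, gap: int = 7,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Append a run of closely spaced SNPs (a splice-signal 'string')."""
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for j in range(n_snps):
        row = _true_snp_row(rng)
        row.update({"contig_id": contig_id, "position": start + j * (gap + 1),
                    "is_true": False})
        rows.append(row)
    out = pd.concat([candidates, pd.DataFrame(rows)], ignore_index=True)
    return out.sort_values(["contig_id", "position"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Miniature GO DAG + gene->GO map


def generate_ontology(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> str:
    """OBO 1.2 text for a small three-namespace DAG.

    Each namespace root gets a layer of children (is_a) and grandchildren
    (is_a), plus one cross-namespace part_of edge from a molecular_function
    branch into biological_process, mirroring how transporter activities
    attach to transport processes.
    """
    rng = config.rng() if rng is None else rng
    stanzas = ["format-version: 1.2\nontology: titmine-synthetic"]
    term_ids: dict[str, list[str]] = {}
    counter = 1
    for root, ns in GO_ROOTS.items():
        stanzas.append(f"[Term]\nid: {root}\nname: {ns}\nnamespace: {ns}")
        ids = []
        n = config.go_terms_per_namespace
        n_level1 = max(2, n // 3)
        level1 = []
        for _ in range(n_level1):
            tid = f"GO:{7000000 + counter:07d}"
            counter += 1
            stanzas.append(
                f"[Term]\nid: {tid}\nname: synthetic term {counter}\n"
                f"namespace: {ns}\nis_a: {root} ! {ns}")
            level1.append(tid)
            ids.append(tid)
        for _ in range(n - n_level1):
            tid = f"GO:{7000000 + counter:07d}"
            counter += 1
            parent = level1[int(rng.integers(len(level1)))]
            extra = ""
            if rng.random() < 0.3 and len(level1) > 1:
                other = level1[int(rng.integers(len(level1)))]
                if other != parent:
                    extra = f"\nis_a: {other} ! synthetic"
            stanzas.append(
                f"[Term]\nid: {tid}\nname: synthetic term {counter}\n"
                f"namespace: {ns}\nis_a: {parent} ! synthetic{extra}")
            ids.append(tid)
        term_ids[ns] = ids
    # one cross-namespace part_of edge (MF leaf -> BP branch)
    mf_leaf = term_ids["molecular_function"][-1]
    bp_branch = term_ids["biological_process"][0]
    stanzas.append(
        f"[Term]\nid: GO:{7999999:07d}\nname: synthetic bridging activity\n"
        f"namespace: molecular_function\nis_a: {mf_leaf} ! synthetic\n"
        f"relationship: part_of {bp_branch} ! synthetic")
    return "\n\n".join(stanzas) + "\n"


def generate_gene2go(genome: GenomeAnnotation, obo_text: str,
                     config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign 1-3 terms to a ``prop_genes_annotated`` fraction of genes."""
    rng = config.rng() if rng is None else rng
    term_ids = [ln.split("id: ")[1].strip() for ln in obo_text.splitlines()
                if ln.startswith("id: GO:") and ln.split("id: ")[1].strip() not in GO_ROOTS]
    rows = []
    for g in genome.genes:
        if rng.random() >= config.prop_genes_annotated:
            continue
        k = int(rng.integers(1, 4))
        for tid in rng.choice(term_ids, size=min(k, len(term_ids)), replace=False):
            rows.append({"gene_id": g.id, "go_id": str(tid)})
    return pd.DataFrame(rows, columns=["gene_id", "go_id"])
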