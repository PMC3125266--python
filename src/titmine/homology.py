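"""Alignment-table mining: best-hit retention, identity clustering,
reciprocal-pair HSP pattern classification, GC accounting, genus-group
contamination triage and small statistical utilities.

Clustering emulates identity-based sequence clustering over a pairwise HSP
table: two contigs are linked when a single HSP reaches the identity cutoff
across the required fraction of the shorter contig, and clusters are the
connected components (single linkage).  Reciprocal contig pairs with multiple
HSPs that are pairwise non-overlapping on both sequences are the disjoint
pattern diagnostic of splice variants or pre-mRNA/mRNA pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

E_VALUE_CUTOFF = 1e-5
CLUSTER_IDENTITY = 95.0
AMBIGUOUS_BASES = set("BDHKMNRSVWY")

GROUP_KINGDOM = {
    "archea": "archea", "bacteria": "bacteria", "algae": "plant",
    "protozoa": "protozoa", "plant": "plant", "fungi": "fungi",
    "invertebrate": "animal", "vertebrate_fish": "animal",
    "vertebrate_amphibians": "animal", "vertebrate_mammalian": "animal",
    "vertebrate_reptiles": "animal", "vertebrate_birds": "animal",
}
VERTEBRATE_GROUPS = {"vertebrate_fish", "vertebrate_amphibians",
                     "vertebrate_mammalian", "vertebrate_reptiles"}


@dataclass(frozen=True)
class PairClassification:
    contig_a: str
    contig_b: str
    n_hsps: int
    pattern: str  # single | multiple_overlapping | multiple_disjoint
    coverage_of_shortest: float
    collinear: bool


def best_hit(records: pd.DataFrame, e_cutoff: float = E_VALUE_CUTOFF) -> pd.DataFrame:
    """Best alignment per query: lowest e-value, ties by highest bit score,
    then first occurrence.  Hits above the e-value cutoff are dropped."""
    kept = records[records["evalue"] <= e_cutoff].copy()
    if kept.empty:
        return kept
    kept["_order"] = np.arange(len(kept))
    kept = kept.sort_values(["qseqid", "evalue", "bitscore", "_order"],
                            ascending=[True, True, False, True], kind="stable")
    out = kept.groupby("qseqid", as_index=False).first()
    return out.drop(columns="_order").reset_index(drop=True)


def cluster_contigs(records: pd.DataFrame, contig_lengths: dict[str, int],
                    identity: float = CLUSTER_IDENTITY,
                    coverage_of_shortest: float = 0.95) -> list[set[str]]:
    """Single-linkage clusters over qualifying HSP edges; singletons omitted.

    An edge requires one HSP with identity >= ``identity`` spanning at least
    ``coverage_of_shortest`` of the shorter contig.
    """
    g = nx.Graph()
    for row in records.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q == s:
            continue
        shortest = min(contig_lengths[q], contig_lengths[s])
        if row.pident >= identity and row.length >= coverage_of_shortest * shortest:
            g.add_edge(q, s)
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    return sorted(comps, key=lambda c: sorted(c)[0])


def _norm(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


def _pairwise_disjoint(intervals: list[tuple[int, int]]) -> bool:
    ordered = sorted(intervals)
    return all(b0 < a1 for (_, b0), (a1, _) in zip(ordered, ordered[1:]))


def classify_pair(hsps: pd.DataFrame) -> PairClassification:
    """Classify the HSP pattern between one reciprocal contig pair.

    multiple_disjoint requires every pair of HSPs to be non-overlapping on
    both sequences; collinearity (same HSP order on both) is reported but not
    required, since an intron retained in one contig breaks collinearity in
    one coordinate system without breaking disjointness.
    """
    if hsps.empty:
        raise ValueError("no HSPs for pair")
    q_int = [_norm(int(r.qstart), int(r.qend)) for r in hsps.itertuples(index=False)]
    s_int = [_norm(int(r.sstart), int(r.send)) for r in hsps.itertuples(index=False)]
    a = str(hsps.iloc[0]["qseqid"])
    b = str(hsps.iloc[0]["sseqid"])
    n = len(hsps)
    best_len = int(hsps["length"].max())
    cov = float("nan")
    if n == 1:
        pattern = "single"
    elif _pairwise_disjoint(q_int) and _pairwise_disjoint(s_int):
        pattern = "multiple_disjoint"
    else:
        pattern = "multiple_overlapping"
    q_order = np.argsort([i[0] for i in q_int])
    s_order = np.argsort([i[0] for i in s_int])
    collinear = bool(np.array_equal(q_order, s_order))
    return PairClassification(contig_a=a, contig_b=b, n_hsps=n, pattern=pattern,
                              coverage_of_shortest=cov, collinear=collinear)


def classify_pairs(records: pd.DataFrame,
                   contig_lengths: dict[str, int] | None = None
                   ) -> pd.DataFrame:
    """Classify every reciprocal pair in a self-vs-self alignment table."""
    rows = []
    records = records[records["qseqid"] != records["sseqid"]].copy()
    key = records.apply(
        lambda r: tuple(sorted((str(r["qseqid"]), str(r["sseqid"])))), axis=1)
    records = records.assign(_pair=key)
    for pair, grp in records.groupby("_pair"):
        cls = classify_pair(grp.drop(columns="_pair"))
        cov = np.nan
        if contig_lengths is not None:
            shortest = min(contig_lengths[pair[0]], contig_lengths[pair[1]])
            cov = float(grp["length"].max()) / shortest
        rows.append({"contig_a": pair[0], "contig_b": pair[1],
                     "n_hsps": cls.n_hsps, "pattern": cls.pattern,
                     "coverage_of_shortest": cov, "collinear": cls.collinear})
    return pd.DataFrame(rows, columns=["contig_a", "contig_b", "n_hsps",
                                       "pattern", "coverage_of_shortest",
                                       "collinear"])


def expression_correlation(contig_a: str, contig_b: str, matrix) -> float | None:
    """Pearson r between the per-tissue read counts of two contigs.

    Returns None when either vector is constant (correlation undefined).
    """
    a = matrix.counts.loc[contig_a].to_numpy(dtype=float)
    b = matrix.counts.loc[contig_b].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def gc_content(sequence: str) -> tuple[float | None, float]:
    """(GC fraction of unambiguous bases, ambiguous fraction of all bases).

    IUPAC ambiguity codes are excluded from the GC denominator; an empty or
    all-ambiguous sequence has no defined GC fraction.
    """
    seq = sequence.upper()
    if not seq:
        return None, 0.0
    ambiguous = sum(1 for b in seq if b in AMBIGUOUS_BASES)
    unambiguous = sum(1 for b in seq if b in "ACGT")
    if ambiguous + unambiguous != len(seq):
        raise ValueError("sequence contains non-IUPAC characters")
    gc = sum(1 for b in seq if b in "GC")
    amb_frac = ambiguous / len(seq)
    if unambiguous == 0:
        return None, amb_frac
    return gc / unambiguous, amb_frac


def load_genus_groups() -> dict[str, str]:
    """Packaged genus -> taxonomic-group map (editable TSV)."""
    text = resources.files("titmine").joinpath("data/genus_groups.tsv").read_text()
    out = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        genus, group = line.split("\t")[:2]
        out[genus] = group
    return out


def genus_triage(hit_genera: list[str],
                 genus_groups: dict[str, str] | None = None) -> str:
    """Contamination triage from the genera a contig aligns to.

    Precedence: any bird hit confirms the contig; any other vertebrate group
    suggests a real gene lacking a bird homologue; hits spanning two or more
    kingdoms are unresolvable short/spurious alignments; a single foreign
    kingdom marks a contamination candidate.
    """
    if genus_groups is None:
        genus_groups = load_genus_groups()
    if not hit_genera:
        return "no_hits"
    groups = set()
    unknown = 0
    for genus in hit_genera:
        grp = genus_groups.get(genus)
        if grp is None:
            unknown += 1
        else:
            groups.add(grp)
    if "vertebrate_birds" in groups:
        return "bird_confirmed"
    if groups & VERTEBRATE_GROUPS:
        return "other_vertebrate"
    kingdoms = {GROUP_KINGDOM[g] for g in groups}
    if len(kingdoms) >= 2:
        return "multi_kingdom"
    if len(kingdoms) == 1:
        return f"single_kingdom:{kingdoms.pop()}"
    return "unknown" if unknown else "no_hits"


def triage_table(contig_hits: dict[str, list[str]],
                 genus_groups: dict[str, str] | None = None) -> pd.DataFrame:
    if genus_groups is None:
        genus_groups = load_genus_groups()
    rows = [{"contig_id": c, "triage": genus_triage(h, genus_groups)}
            for c, h in contig_hits.items()]
    return pd.DataFrame(rows, columns=["contig_id", "triage"])


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Two-sample t statistic with unequal variances (Welch-Satterthwaite)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mean_read_length(total_bases: float, n_reads: float) -> float:
    """Mean sequence length from summary totals."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    return total_bases / n_reads
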