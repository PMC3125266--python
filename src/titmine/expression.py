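"""Tissue-specificity scoring: TPM standardisation, the tau index, and
breadth-of-expression classes.

TPM standardises each contig's read count to reads per million within its
tissue library: ``TPM_i = reads_i * 1e6 / library_i``.  The tau index,

    tau = sum_i (1 - TPM_i / TPM_max) / (N - 1),

is 0 for uniform expression and approaches 1 for single-tissue expression.
To damp sampling noise at low counts every TPM value is floored at 2 before
tau is computed, so a contig expressed in exactly one tissue has
``tau = 1 - 2 / TPM_max`` in closed form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, TauResult

TAU_FLOOR = 2.0
MIN_SPECIFIC_READS = 4
TAU_SPECIFIC_CUTOFF = 0.8


def compute_tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads-per-million per (contig, tissue); no flooring applied here."""
    libs = matrix.library_sizes.to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return matrix.counts * 1e6 / libs


def compute_tau(tpm_row, floor: float = TAU_FLOOR) -> tuple[float | None, float]:
    """(tau, tpm_max) for one contig's per-tissue TPM vector.

    Returns ``tau = None`` if the contig is unexpressed everywhere (flooring
    an all-zero row would masquerade as perfectly uniform expression).
    """
    tpm = np.asarray(tpm_row, dtype=float)
    if tpm.size < 2:
        raise ValueError("tau needs at least two tissues")
    if (tpm < 0).any():
        raise ValueError("negative TPM")
    if not tpm.any():
        return None, 0.0
    floored = np.maximum(tpm, floor)
    tpm_max = float(floored.max())
    tau = float(np.sum(1.0 - floored / tpm_max) / (tpm.size - 1))
    return tau, tpm_max


def classify_breadth(count_row, min_specific_reads: int = MIN_SPECIFIC_READS) -> str:
    """Breadth label from raw per-tissue counts.

    ubiquitous: every tissue contributes >= 1 read; tissue_specific:<t>: all
    reads from tissue t with at least ``min_specific_reads`` of them;
    absent: no reads anywhere; intermediate: everything else.
    """
    counts = np.asarray(count_row)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if not counts.any():
        return "absent"
    if (counts >= 1).all():
        return "ubiquitous"
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 1 and counts[nonzero[0]] >= min_specific_reads:
        try:
            name = count_row.index[nonzero[0]]  # pandas Series
        except AttributeError:
            name = nonzero[0]
        return f"tissue_specific:{name}"
    return "intermediate"


def score_matrix(matrix: ExpressionMatrix, floor: float = TAU_FLOOR,
                 min_specific_reads: int = MIN_SPECIFIC_READS) -> list[TauResult]:
    """Per-contig tau + breadth over a whole expression matrix."""
    tpm = compute_tpm(matrix)
    results = []
    for cid in matrix.contigs:
        row = tpm.loc[cid]
        tau, tpm_max = compute_tau(row, floor=floor)
        breadth = classify_breadth(matrix.counts.loc[cid],
                                   min_specific_reads=min_specific_reads)
        results.append(TauResult(contig_id=cid, tau=tau,
                                 tpm=tuple(float(x) for x in row),
                                 tpm_max=tpm_max, breadth=breadth))
    return results


def results_frame(results: list[TauResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "contig_id": [r.contig_id for r in results],
        "tau": [r.tau if r.tau is not None else np.nan for r in results],
        "tpm_max": [r.tpm_max for r in results],
        "breadth": [r.breadth for r in results],
    })


def breadth_summary(matrix: ExpressionMatrix, floor: float = TAU_FLOOR,
                    min_specific_reads: int = MIN_SPECIFIC_READS,
                    tau_cutoff: float = TAU_SPECIFIC_CUTOFF) -> pd.DataFrame:
    """Per-tissue table of tissue-specific contig counts (and how many of
    those have tau >= cutoff), plus ubiquitous/intermediate/absent rows.

    The counts partition the contig set: per-tissue specific counts plus the
    ubiquitous, intermediate and absent rows sum to the number of contigs.
    """
    results = score_matrix(matrix, floor=floor,
                           min_specific_reads=min_specific_reads)
    rows = []
    other = {"ubiquitous": 0, "intermediate": 0, "absent": 0}
    per_tissue = {t: [0, 0] for t in matrix.tissues}
    for r in results:
        if r.breadth.startswith("tissue_specific:"):
            t = r.breadth.split(":", 1)[1]
            per_tissue[t][0] += 1
            if r.tau is not None and r.tau >= tau_cutoff:
                per_tissue[t][1] += 1
        else:
            other[r.breadth] += 1
    for t in matrix.tissues:
        rows.append({"tissue": t, "tissue_specific": per_tissue[t][0],
                     "tau_ge_cutoff": per_tissue[t][1]})
    frame = pd.DataFrame(rows)
    frame.attrs.update(other)
    frame.attrs["n_contigs"] = len(matrix.contigs)
    return frame


def totalise_breadth(per_tissue_specific, per_tissue_tau_high=None) -> dict:
    """Column totaliser for a breadth summary (or any per-tissue count table)."""
    out = {"tissue_specific_total": int(np.sum(per_tissue_specific))}
    if per_tissue_tau_high is not None:
        out["tau_high_total"] = int(np.sum(per_tissue_tau_high))
    return out


def ubiquitous_share(n_ubiquitous: int, n_contigs: int) -> float:
    """Fraction of contigs expressed in every tissue."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    return n_ubiquitous / n_contigs


def estimate_coverage(aligned_bases: float, reference_transcriptome_bases: float) -> float:
    """Fold coverage of a reference transcriptome by the aligned read bases."""
    if reference_transcriptome_bases <= 0:
        raise ValueError("reference size must be positive")
    return aligned_bases / reference_transcriptome_bases
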