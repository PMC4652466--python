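"""OTU filtering, normalization, log transform, and differential abundance.

Filtering and normalization operate on one study group at a time: an OTU is
discarded when its total read count over the group is below ``min_reads`` or
it is present (count > 0) in less than ``min_prevalence`` of the group's
samples.  Retained counts are converted to per-sample relative abundances and
log10-transformed, with zeros replaced by a pseudocount before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_abundance import AbundanceMatrix, AbundanceValidationError

__all__ = [
    "NormalizedMatrix",
    "DiffAbundanceScores",
    "FilterLog",
    "filter_otus",
    "normalize_and_log",
    "differential_abundance",
]

DEFAULT_MIN_READS = 100
DEFAULT_MIN_PREVALENCE = 0.20


@dataclass
class FilterLog:
    """Discarded OTUs with the reason each failed."""

    records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["otu_id", "total_reads", "prevalence", "reason"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedMatrix:
    """Log10-transformed relative abundances.

    ``values[i, j] = log10(counts[i, j] / total_i)`` with zero counts replaced
    by ``pseudocount`` (on the relative-abundance scale) before the log.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AbundanceValidationError("normalized values must be finite")
        if self.pseudocount <= 0:
            raise AbundanceValidationError("pseudocount must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mean_log_abundance(self) -> np.ndarray:
        """Per-OTU mean log abundance across samples (node-size annotation)."""
        return self.values.mean(axis=0)


@dataclass
class DiffAbundanceScores:
    """Per-OTU two-group differential-abundance evidence.

    ``heat`` is ``1 - p`` clamped to [0, 1]: 1 for the most significant
    difference (hottest/red), 0 for none (coolest/blue).
    """

    otu_ids: list[str]
    p_values: np.ndarray
    heat: np.ndarray


def filter_otus(
    m: AbundanceMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
) -> tuple[AbundanceMatrix, FilterLog]:
    """Discard low-signal OTUs from a single-group matrix.

    An OTU is kept iff its total reads >= ``min_reads`` AND it is present in
    at least ``min_prevalence`` of the samples (both inequalities non-strict,
    i.e. an OTU is discarded iff total < min_reads OR prevalence <
    min_prevalence).

    Returns the filtered matrix and a log of discarded OTUs with reasons.
    """
    if m.n_samples == 0 or m.n_otus == 0:
        raise AbundanceValidationError("cannot filter an empty matrix")
    totals = m.counts.sum(axis=0)
    prevalence = (m.counts > 0).mean(axis=0)
    keep = (totals >= min_reads) & (prevalence >= min_prevalence)

    records = []
    for j in np.flatnonzero(~keep):
        reasons = []
        if totals[j] < min_reads:
            reasons.append(f"total_reads<{min_reads}")
        if prevalence[j] < min_prevalence:
            reasons.append(f"prevalence<{min_prevalence:g}")
        records.append(
            {
                "otu_id": m.otu_ids[j],
                "total_reads": int(totals[j]),
                "prevalence": float(prevalence[j]),
                "reason": ";".join(reasons),
            }
        )
    kept_idx = np.flatnonzero(keep)
    filtered = AbundanceMatrix(
        list(m.sample_ids),
        [m.otu_ids[j] for j in kept_idx],
        m.counts[:, kept_idx].copy(),
        dict(m.group_of),
    )
    return filtered, FilterLog(records)


def normalize_and_log(
    m: AbundanceMatrix, pseudocount: float | str = "auto"
) -> NormalizedMatrix:
    """Per-sample relative abundance followed by a base-10 log transform.

    Zeros are replaced by ``pseudocount`` on the relative-abundance scale;
    ``"auto"`` uses half the smallest nonzero relative abundance in the
    matrix.

    Raises
    ------
    AbundanceValidationError
        If any sample has an all-zero row (total count 0); the message names
        the first offending sample.
    """
    totals = m.counts.sum(axis=1, dtype=float)
    if np.any(totals == 0):
        bad = m.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise AbundanceValidationError(f"sample {bad!r} has zero total count")
    rel = m.counts / totals[:, None]
    if pseudocount == "auto":
        nonzero = rel[rel > 0]
        if nonzero.size == 0:
            raise AbundanceValidationError("matrix has no nonzero counts")
        pc = float(nonzero.min()) / 2.0
    else:
        pc = float(pseudocount)
        if pc <= 0:
            raise AbundanceValidationError("pseudocount must be positive")
    values = np.log10(np.where(rel > 0, rel, pc))
    return NormalizedMatrix(list(m.sample_ids), list(m.otu_ids), values, pc)


def differential_abundance(
    a: NormalizedMatrix, b: NormalizedMatrix
) -> DiffAbundanceScores:
    """Two-sided Welch t-test per OTU between two groups of samples.

    Both matrices must share the same OTU set (same order) and have at least
    two samples each.  Returns p-values and the heat scalar ``1 - p``.
    """
    if a.otu_ids != b.otu_ids:
        raise AbundanceValidationError(
            "OTU sets differ between groups; align columns before testing"
        )
    if a.n_samples < 2 or b.n_samples < 2:
        raise AbundanceValidationError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a.values, b.values, axis=0, equal_var=False)
    # identical constant columns give nan (0/0 statistic): no evidence, p = 1
    p = np.where(np.isnan(p), 1.0, p)
    heat = np.clip(1.0 - p, 0.0, 1.0)
    return DiffAbundanceScores(list(a.otu_ids), p, heat)
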