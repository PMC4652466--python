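"""Reading, writing, and subsetting OTU abundance tables.

The central object is :class:`AbundanceMatrix`: a samples x OTUs table of
non-negative integer read counts together with a mapping from sample ID to
study group.  Tables are tab-separated by default (header row of OTU labels,
first column of sample IDs); a comma dialect and an OTUs-as-rows orientation
are accepted via flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "read_abundance_table",
    "read_group_assignment",
    "write_abundance_table",
    "write_group_assignment",
    "subset_group",
]


class AbundanceValidationError(ValueError):
    """Raised when a table violates the abundance-matrix contract."""


@dataclass
class AbundanceMatrix:
    """Samples x OTUs count table with per-sample group labels.

    Attributes
    ----------
    sample_ids : list of str
        Row identifiers, unique, in table order.
    otu_ids : list of str
        Column labels, unique (duplicates are disambiguated on read by
        appending an integer suffix in order of first appearance).
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integer read counts.
    group_of : dict
        Mapping sample_id -> group label.  May be missing entries for
        samples absent from the metadata; group-aware operations require
        complete coverage.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise AbundanceValidationError("counts must be a 2-D array")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise AbundanceValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise AbundanceValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise AbundanceValidationError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise AbundanceValidationError(f"duplicate sample IDs: {dupes}")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = _duplicates(self.otu_ids)
            raise AbundanceValidationError(f"duplicate OTU IDs: {dupes}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            g = self.group_of.get(s)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def _disambiguate(labels: list[str]) -> list[str]:
    """Append ``_k`` (k = 1, 2, ... in order of first appearance) to labels
    that occur more than once; unique labels pass through unchanged."""
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    next_idx: dict[str, int] = {}
    out = []
    for lab in labels:
        if counts[lab] > 1:
            next_idx[lab] = next_idx.get(lab, 0) + 1
            out.append(f"{lab}_{next_idx[lab]}")
        else:
            out.append(lab)
    return out


def read_group_assignment(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a sample metadata table with ``sample_id`` and ``group`` columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise AbundanceValidationError(
            f"metadata must have sample_id and group columns, got {list(df.columns)}"
        )
    sids = df[cols["sample_id"]].tolist()
    if len(set(sids)) != len(sids):
        raise AbundanceValidationError(
            f"duplicate sample IDs in metadata: {_duplicates(sids)}"
        )
    mapping = dict(zip(sids, df[cols["group"]].tolist()))
    if not mapping:
        raise AbundanceValidationError("metadata table is empty")
    return mapping


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = "\t",
    transpose: bool = False,
) -> AbundanceMatrix:
    """Read an abundance table (and optional sample metadata).

    Parameters
    ----------
    path
        Delimited text table: header row of OTU labels, first column of
        sample IDs, integer counts.
    metadata_path
        Optional table with ``sample_id`` and ``group`` columns.
    sep
        Field delimiter; tab by default.
    transpose
        If True the file is OTUs-as-rows and is transposed on read.

    Raises
    ------
    FileNotFoundError
        Missing input file.
    AbundanceValidationError
        Non-numeric cell (the error names its row and column), duplicate
        sample IDs, or malformed metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"abundance table not found: {path}")
    # header parsed by hand: pandas mangles duplicate column labels, which
    # must instead be disambiguated with integer suffixes
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, skiprows=1,
                      header=None, names=range(len(header)))
    raw.columns = header
    if transpose:
        raw = raw.T
        raw.columns = [str(c) for c in raw.columns]
    sample_ids = [str(s) for s in raw.index.tolist()]
    otu_ids = _disambiguate([str(c) for c in raw.columns.tolist()])
    if len(set(sample_ids)) != len(sample_ids):
        raise AbundanceValidationError(
            f"duplicate sample IDs in {path.name}: {_duplicates(sample_ids)}"
        )
    counts = np.empty((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        bad = parsed.isna() & raw.iloc[:, j].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise AbundanceValidationError(
                f"non-numeric count {raw.iloc[i, j]!r} at sample "
                f"{sample_ids[i]!r}, OTU {otu_ids[j]!r}"
            )
        if parsed.isna().any():
            i = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise AbundanceValidationError(
                f"missing count at sample {sample_ids[i]!r}, OTU {otu_ids[j]!r}"
            )
        counts[:, j] = parsed.to_numpy()

    group_of: dict[str, str] = {}
    if metadata_path is not None:
        group_of = read_group_assignment(metadata_path, sep=sep)
        missing = [s for s in sample_ids if s not in group_of]
        if missing:
            warnings.warn(
                f"{len(missing)} sample(s) absent from metadata: {missing[:5]}",
                stacklevel=2,
            )
    return AbundanceMatrix(sample_ids, otu_ids, counts, group_of)


def write_abundance_table(
    m: AbundanceMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    """Write the matrix (and optionally its metadata) in the read dialect."""
    m.to_frame().to_csv(path, sep=sep, index_label="sample_id")
    if metadata_path is not None:
        write_group_assignment(m.group_of, metadata_path, sep=sep)


def write_group_assignment(
    group_of: dict[str, str], path: str | Path, sep: str = "\t"
) -> None:
    pd.DataFrame(
        {"sample_id": list(group_of), "group": list(group_of.values())}
    ).to_csv(path, sep=sep, index=False)


def subset_group(m: AbundanceMatrix, group: str) -> AbundanceMatrix:
    """Restrict to the samples of one study group; OTU columns unchanged.

    Raises
    ------
    AbundanceValidationError
        If no sample carries the requested group label; the message lists
        the available groups.
    """
    keep = [i for i, s in enumerate(m.sample_ids) if m.group_of.get(s) == group]
    if not keep:
        raise AbundanceValidationError(
            f"group {group!r} not found; available groups: {m.groups()}"
        )
    sample_ids = [m.sample_ids[i] for i in keep]
    return AbundanceMatrix(
        sample_ids,
        list(m.otu_ids),
        m.counts[keep, :].copy(),
        {s: m.group_of[s] for s in sample_ids},
    )
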