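"""Reading, validation and writing of count matrices, sample designs and Ct tables.

All on-disk formats are tab-separated UTF-8 text with a mandatory header row
and no quoting; missing adjusted p-values are encoded as ``NA``. Gene and
sample identifiers are opaque strings and must be unique within a table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: The four levels of the factorial treatment factor, in canonical order:
#: vehicle control, single treatment A, single treatment B, combined A+B.
CONDITIONS = ("VEHICLE", "TRT_A", "TRT_B", "COMBO")

RESULT_COLUMNS = ("gene_id", "base_mean", "log2fc", "se", "wald_stat", "pvalue", "padj")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class ParseError(ValueError):
    """A cell of an input table cannot be interpreted."""


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids : tuple of str
        Row identifiers, unique, in matrix order.
    sample_ids : tuple of str
        Column identifiers, unique, in matrix order.
    counts : ndarray of int
        Shape ``(len(gene_ids), len(sample_ids))``, all entries >= 0.
    """

    gene_ids: tuple
    sample_ids: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts.astype(float))):
                raise ValidationError("count matrix contains non-finite entries")
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ParseError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        """Build from a DataFrame whose index is gene ids and columns sample ids."""
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=list(self.gene_ids), columns=list(self.sample_ids))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Tuning knobs shared by the differential-expression stages.

    alpha is the FDR threshold for calling a gene differentially expressed
    (strict ``padj < alpha``); min_total_count is the expression filter: genes
    whose raw counts sum to less than this across all samples are reported but
    not tested (missing ``padj``).
    """

    alpha: float = 0.05
    min_total_count: int = 10
    seed: int = 0
    output_dir: str = "comboseq_out"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_total_count < 0:
            raise ValidationError("min_total_count must be >= 0")


def read_counts(path) -> CountMatrix:
    """Read a genes x samples count matrix from a tab-separated file.

    The first column holds gene identifiers; the header row holds sample
    identifiers. Row and column order are preserved. Duplicate identifiers,
    negative or non-integer cells raise with the offending coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index.astype(str), "gene")
    _check_unique(df.columns.astype(str), "sample")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            i = int(np.flatnonzero(num.isna().to_numpy())[0])
            raise ParseError(
                f"{path.name}: unparseable count at gene {df.index[i]!r}, sample {col!r}: "
                f"{df[col].iloc[i]!r}"
            )
        arr = num.to_numpy()
        if np.any(np.mod(arr, 1) != 0):
            i = int(np.flatnonzero(np.mod(arr, 1) != 0)[0])
            raise ParseError(f"{path.name}: non-integer count at gene {df.index[i]!r}, sample {col!r}")
        values[:, j] = arr.astype(np.int64)
    return CountMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), values)


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix as TSV; inverse of :func:`read_counts`."""
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    """Read a sample design table (columns sample_id, condition, replicate).

    Condition labels are folded case-insensitively onto the four-level factor
    :data:`CONDITIONS`; any other label is an error. A condition with fewer
    than two replicates triggers a warning here and an error only when a
    differential-expression fit is attempted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return validate_design(df)


def validate_design(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design table lacks required column(s): {sorted(missing)}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(df["sample_id"], "sample")
    cond = df["condition"].astype(str).str.strip().str.upper()
    unknown = sorted(set(cond) - set(CONDITIONS))
    if unknown:
        raise ValidationError(
            f"unknown condition label(s) {unknown}; allowed labels (case-insensitive): {list(CONDITIONS)}"
        )
    df["condition"] = cond
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (np.mod(rep, 1) != 0).any():
        raise ValidationError("replicate indices must be positive integers")
    df["replicate"] = rep.astype(int)
    low = [c for c in sorted(set(cond)) if (cond == c).sum() < 2]
    if low:
        warnings.warn(
            f"condition(s) with fewer than 2 replicates: {low}; "
            "differential expression will refuse to run on them",
            stacklevel=2,
        )
    return df


def check_design_matches(cm: CountMatrix, design: pd.DataFrame) -> None:
    """Require the design's samples and the count matrix columns to coincide."""
    d = set(design["sample_id"])
    c = set(cm.sample_ids)
    if d != c:
        only_d = sorted(d - c)
        only_c = sorted(c - d)
        raise ValidationError(
            f"design/counts sample mismatch: in design only {only_d}, in counts only {only_c}"
        )


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct table (columns sample_id, condition, gene, ct, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "gene": str})
    required = {"sample_id", "condition", "gene", "ct", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table lacks required column(s): {sorted(missing)}")
    df = df.copy()
    df["condition"] = df["condition"].astype(str).str.strip().str.upper()
    unknown = sorted(set(df["condition"]) - set(CONDITIONS))
    if unknown:
        raise ValidationError(
            f"unknown condition label(s) {unknown}; allowed labels (case-insensitive): {list(CONDITIONS)}"
        )
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any():
        i = int(np.flatnonzero(ct.isna().to_numpy())[0])
        raise ParseError(f"unparseable Ct value in row {i}")
    df["ct"] = ct.astype(float)
    return df


def _format_result_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    cols = [c for c in RESULT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    return out[cols]


def write_results(tables: Mapping[str, pd.DataFrame], summary: Mapping, out_dir) -> list:
    """Write per-contrast result tables and a machine-readable summary.

    One TSV per named table plus ``summary.json`` (sorted keys, so re-running
    with identical inputs yields a byte-identical file). Returns the manifest
    of written file paths, summary last.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list = []
    for name in sorted(tables):
        p = out / f"{name}.tsv"
        _format_result_table(tables[name]).to_csv(p, sep="\t", index=False, na_rep="NA")
        manifest.append(str(p))
    sp = out / "summary.json"
    with open(sp, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    manifest.append(str(sp))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
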