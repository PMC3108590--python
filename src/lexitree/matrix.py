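"""Labeled symmetric distance matrices and their on-disk formats.

A :class:`DistanceMatrix` couples an ordered tuple of language labels with a
square numpy array of pairwise dissimilarities. Two text formats are
supported: a PHYLIP-style square matrix (taxon count on the first line, one
labeled row per taxon) and a long-format TSV with columns
``lang_a``, ``lang_b``, ``distance`` listing each unordered pair once.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError

__all__ = ["DistanceMatrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal matrix of dissimilarities between languages."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    # -- access ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.index(x) for x in keep]
        return DistanceMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    # -- I/O ------------------------------------------------------------

    def to_phylip(self, path: str | os.PathLike | None = None) -> str:
        """Serialize as a PHYLIP-style square matrix; write to *path* if given."""
        buf = io.StringIO()
        buf.write(f"{self.n}\n")
        for label, row in zip(self.labels, self.values):
            cells = "\t".join(f"{x:.10g}" for x in row)
            buf.write(f"{label}\t{cells}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_phylip(cls, source: str | os.PathLike) -> "DistanceMatrix":
        """Read a PHYLIP-style square matrix from a path or a literal string."""
        text = _read_text(source)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise DataFormatError("empty distance-matrix file")
        try:
            n = int(lines[0].split()[0])
        except ValueError as exc:
            raise DataFormatError(
                "first line of a PHYLIP matrix must be the taxon count"
            ) from exc
        if len(lines) - 1 != n:
            raise DataFormatError(
                f"expected {n} matrix rows, found {len(lines) - 1}"
            )
        labels, rows = [], []
        for ln in lines[1:]:
            parts = ln.split()
            if len(parts) != n + 1:
                raise DataFormatError(f"malformed matrix row: {ln!r}")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(tuple(labels), np.array(rows))

    def to_long_tsv(self, path: str | os.PathLike | None = None) -> pd.DataFrame:
        """Long format: one row per unordered pair (``lang_a``, ``lang_b``, ``distance``)."""
        recs = [
            (self.labels[i], self.labels[j], self.values[i, j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]
        df = pd.DataFrame(recs, columns=["lang_a", "lang_b", "distance"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df

    @classmethod
    def from_long_tsv(cls, source: str | os.PathLike) -> "DistanceMatrix":
        df = pd.read_csv(source, sep="\t", dtype={"lang_a": str, "lang_b": str})
        required = {"lang_a", "lang_b", "distance"}
        if not required.issubset(df.columns):
            raise DataFormatError(
                f"long-format matrix needs columns {sorted(required)}"
            )
        labels: list[str] = []
        for col in ("lang_a", "lang_b"):
            for x in df[col]:
                if x not in labels:
                    labels.append(x)
        n = len(labels)
        idx = {x: i for i, x in enumerate(labels)}
        values = np.zeros((n, n))
        seen = np.eye(n, dtype=bool)
        for a, b, d in df.itertuples(index=False):
            i, j = idx[a], idx[b]
            values[i, j] = values[j, i] = float(d)
            seen[i, j] = seen[j, i] = True
        if not seen.all():
            raise DataFormatError("long-format matrix is missing some pairs")
        return cls(tuple(labels), values)


def _read_text(source: str | os.PathLike) -> str:
    if isinstance(source, str) and "\n" in source:
        return source
    with open(source, encoding="utf-8") as fh:
        return fh.read()
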