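"""Core data containers and delimited-text IO for two-class expression data.

The universal input is an :class:`ExpressionDataset`: an ``n x d`` matrix of
expression intensities, one class label per sample in ``{-1, +1}`` and unique
gene/sample identifiers.  Loaders accept TSV/CSV in either orientation
(samples in rows or genes in rows) and normalise common label encodings
(``{0, 1}``, ``"normal"``/``"cancer"``) to the internal ``{-1, +1}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "FeatureSet",
    "load_dataset",
    "write_dataset",
    "write_report",
]

#: Accepted text encodings of the two classes, applied case-insensitively at
#: load time only.  Internal code sees nothing but -1 / +1.
LABEL_ALIASES = {
    "-1": -1,
    "1": 1,
    "+1": 1,
    "0": -1,
    "normal": -1,
    "cancer": 1,
    "tumor": 1,
    "tumour": 1,
}


class DatasetError(ValueError):
    """Raised when an input matrix violates the dataset contract."""


def _normalize_label(raw) -> int:
    key = str(raw).strip().lower()
    if key.endswith(".0"):
        key = key[:-2]
    try:
        return LABEL_ALIASES[key]
    except KeyError:
        raise DatasetError(
            f"unrecognised class label {raw!r}; expected one of "
            f"{sorted(set(LABEL_ALIASES))}"
        ) from None


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with binary class labels.

    Parameters
    ----------
    values
        ``(n_samples, n_genes)`` float matrix, no missing entries.
    labels
        Per-sample class in ``{-1, +1}``.
    gene_ids, sample_ids
        Unique identifier strings for columns and rows respectively.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D samples x genes matrix")
        n, d = self.values.shape
        if self.labels.shape != (n,):
            raise DatasetError("one label per sample required")
        if self.gene_ids.shape != (d,):
            raise DatasetError("one gene id per column required")
        if self.sample_ids.shape != (n,):
            raise DatasetError("one sample id per row required")
        if not np.all(np.isin(self.labels, (-1, 1))):
            bad = sorted(set(self.labels) - {-1, 1})
            raise DatasetError(f"labels must be -1/+1; found {bad}")
        if len(set(self.gene_ids)) != d:
            raise DatasetError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != n:
            raise DatasetError("sample identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("expression matrix contains missing/non-finite values")
        if n and len(set(self.labels)) == 1:
            warnings.warn(
                "dataset contains a single class; classifiers cannot be fit on it",
                stacklevel=3,
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def restrict(self, genes: Sequence[int]) -> "ExpressionDataset":
        """Return a copy keeping only the given gene columns, in that order."""
        idx = np.asarray(genes, dtype=int)
        return ExpressionDataset(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            gene_ids=self.gene_ids[idx],
            sample_ids=self.sample_ids.copy(),
        )

    def class_split(self) -> tuple[np.ndarray, np.ndarray]:
        """Values of the negative-class and positive-class samples."""
        return self.values[self.labels == -1], self.values[self.labels == 1]

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()[:16]


@dataclass
class FeatureSet:
    """An ordered selection of genes (most relevant first).

    ``indices`` are positions in the ORIGINAL gene order of the dataset the
    selection was made from; ``gene_ids`` are the matching identifiers.
    """

    indices: np.ndarray
    gene_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.gene_ids is not None:
            self.gene_ids = np.asarray(self.gene_ids, dtype=object)
            if self.gene_ids.shape != self.indices.shape:
                raise DatasetError("gene_ids must align with indices")
        if len(set(self.indices.tolist())) != self.indices.size:
            raise DatasetError("selected gene indices must be unique")

    @property
    def f0(self) -> int:
        return int(self.indices.size)

    def __len__(self) -> int:
        return self.f0


def _read_table(path, delimiter=None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)[1:]
    dupes = sorted({name for name in header if header.count(name) > 1})
    if dupes:
        # pandas would silently mangle these to name.1, name.2, ...
        raise DatasetError(f"duplicate gene identifiers: {dupes}")
    return pd.read_csv(path, sep=delimiter, index_col=0, dtype=object)


def load_dataset(
    path,
    orientation: str = "samples-in-rows",
    label_field: str = "label",
    missing: str = "error",
    rng: np.random.Generator | None = None,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load a labelled expression matrix from delimited text.

    Parameters
    ----------
    orientation
        ``"samples-in-rows"``: header = gene ids plus a ``label_field``
        column, first column = sample ids.  ``"genes-in-rows"``: first
        column = gene ids, header = sample ids, plus one row whose id equals
        ``label_field`` holding per-sample labels.
    missing
        ``"error"`` (default) rejects non-numeric/empty cells;
        ``"substitute"`` replaces each invalid cell with a fresh uniform
        draw on [0, 1) (a new draw per cell per call), mirroring the common
        treatment of invalid microarray intensities.
    rng
        Source of randomness for ``missing="substitute"``.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _read_table(path, delimiter)
    if orientation == "genes-in-rows":
        if label_field not in frame.index:
            raise DatasetError(f"label row {label_field!r} not found in {path}")
        frame = frame.T
    if label_field not in frame.columns:
        raise DatasetError(f"label column {label_field!r} not found in {path}")

    labels = np.array([_normalize_label(v) for v in frame[label_field]])
    expr = frame.drop(columns=[label_field])
    gene_ids = expr.columns.to_numpy(dtype=object)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise DatasetError(f"duplicate gene identifiers: {dupes}")

    def _coerce(cell):
        # python float() parses round-trip decimals exactly, unlike the
        # fast (lossy) parser behind pd.to_numeric
        try:
            return float(cell)
        except (TypeError, ValueError):
            return float("nan")

    values = expr.map(_coerce).to_numpy(dtype=float)
    invalid = ~np.isfinite(values)
    if invalid.any():
        if missing == "error":
            r, c = np.argwhere(invalid)[0]
            raise DatasetError(
                f"non-numeric or missing value at sample {expr.index[r]!r}, "
                f"gene {gene_ids[c]!r} (and {invalid.sum() - 1} more)"
            )
        if missing != "substitute":
            raise ValueError(f"unknown missing-value policy {missing!r}")
        rng = np.random.default_rng() if rng is None else rng
        values[invalid] = rng.uniform(0.0, 1.0, size=int(invalid.sum()))

    return ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=gene_ids,
        sample_ids=expr.index.to_numpy(dtype=object),
    )


def write_dataset(ds: ExpressionDataset, path, label_field: str = "label") -> None:
    """Write samples-in-rows delimited text that round-trips exactly.

    Floats are printed with enough significant digits that
    ``load(write(ds))`` reproduces ``ds.values`` bit for bit.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    frame.insert(0, label_field, ds.labels)
    # shortest decimal that round-trips each double exactly
    frame.to_csv(
        path, sep=sep, float_format=lambda v: repr(float(v)),
        index_label="sample_id",
    )


def write_report(
    feature_set: FeatureSet,
    curve,
    fits: Iterable,
    outdir,
    summary_extra: dict | None = None,
) -> dict:
    """Persist an extraction run: gene list, margin curve, fit errors, summary.

    Writes, inside ``outdir``:

    - ``selected_genes.txt`` — one gene id per line, rank order;
    - ``margin_curve.tsv`` — columns ``i`` (1-based) and ``W``;
    - ``fit_errors.tsv`` — columns ``f`` (candidate breakpoint) and ``epsilon``;
    - ``summary.json`` — ``f0``, selected ids, and any extra parameters/seed.

    Returns the summary dict that was written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    w_values = np.asarray(getattr(curve, "values", curve), dtype=float)

    ids = feature_set.gene_ids
    if ids is None:
        ids = np.array([str(i) for i in feature_set.indices], dtype=object)
    (outdir / "selected_genes.txt").write_text(
        "".join(f"{g}\n" for g in ids)
    )

    pd.DataFrame(
        {"i": np.arange(1, w_values.size + 1), "W": w_values}
    ).to_csv(outdir / "margin_curve.tsv", sep="\t", index=False, float_format="%.17g")

    fit_rows = [(int(f.c), float(f.epsilon)) for f in fits]
    pd.DataFrame(fit_rows, columns=["f", "epsilon"]).to_csv(
        outdir / "fit_errors.tsv", sep="\t", index=False, float_format="%.17g"
    )

    summary = {
        "f0": feature_set.f0,
        "selected_gene_ids": [str(g) for g in ids],
        "selected_indices": [int(i) for i in feature_set.indices],
        "f_max": int(w_values.size),
    }
    if summary_extra:
        summary.update(summary_extra)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
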