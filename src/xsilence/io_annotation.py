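"""Expression-table and probe-annotation I/O.

The universal data carrier is :class:`ExpressionMatrix`: a probes-by-samples
(or genes-by-samples) table of non-negative linear-scale intensities with a
species and tissue tag.  Probe annotations map an opaque probe id to a gene
symbol (possibly empty, meaning unannotated) and a chromosome label in
``{"1".."22", "X", "Y", "other"}``.

All tables are plain TSV: UTF-8, tab-separated, ``.`` decimal, no quoting.
An annotation file has exactly the columns ``probe_id``, ``gene_symbol`` and
``chromosome``; an expression table has a header row of sample ids and a
first column of probe ids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

AUTOSOME_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOME_LABELS: tuple[str, ...] = AUTOSOME_LABELS + ("X", "Y", "other")
ANNOTATION_COLUMNS: tuple[str, ...] = ("probe_id", "gene_symbol", "chromosome")

#: float format used for every table written by this package; chosen so that
#: a write/read round trip preserves at least 6 significant digits.
FLOAT_FORMAT = "%.10g"


@dataclass
class ExpressionMatrix:
    """Probes (rows) x samples (columns) of non-negative linear intensities.

    Parameters
    ----------
    values
        DataFrame with unique row ids (probes or gene symbols) and unique
        sample ids as columns.  All entries must be finite and >= 0.
    species, tissue
        Free-text tags carried through the pipeline (e.g. ``"chimpanzee"``,
        ``"testis"``).
    """

    values: pd.DataFrame
    species: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise FormatError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative intensity {arr[r, c]!r} at probe {v.index[r]!r}, "
                f"sample {v.columns[c]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a new matrix with the same tags and different values."""
        return ExpressionMatrix(values=values, species=self.species, tissue=self.tissue)


def normalize_chromosome(label: object) -> str:
    """Normalize a chromosome label to the canonical set.

    ``"chr3"`` -> ``"3"``, ``"x"``/``"chrX"`` -> ``"X"``; anything outside
    ``1..22, X, Y`` (e.g. ``"MT"``, ``"Un"``) maps to ``"other"``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y"):
        return s.upper()
    if s in AUTOSOME_LABELS:
        return s
    return "other"


def read_expression_table(
    path: str | PathLike, species: str = "", tissue: str = ""
) -> ExpressionMatrix:
    """Read a TSV expression table (first column probe ids, header sample ids).

    Raises
    ------
    FormatError
        On duplicate probe ids, non-numeric or negative values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(values=df, species=species, tissue=tissue)


def write_expression_table(matrix: ExpressionMatrix, path: str | PathLike) -> None:
    """Write a matrix as TSV; inverse of :func:`read_expression_table`."""
    matrix.values.to_csv(
        path, sep="\t", index_label="probe_id", float_format=FLOAT_FORMAT
    )


def read_annotation(path: str | PathLike) -> pd.DataFrame:
    """Read a 3-column probe annotation table.

    Returns a DataFrame indexed by ``probe_id`` with columns ``gene_symbol``
    (empty string = unannotated) and ``chromosome`` (normalized labels;
    unknown labels are mapped to ``"other"`` and counted in a warning).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation {path} is missing column(s) {missing}")
    df = df[list(ANNOTATION_COLUMNS)].copy()
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe id {dup!r} in annotation {path}")
    raw = df["chromosome"]
    norm = raw.map(normalize_chromosome)
    n_unknown = int(((norm == "other") & (raw.str.strip().str.lower() != "other")).sum())
    if n_unknown:
        logger.warning(
            "%d annotation chromosome label(s) outside 1..22/X/Y mapped to 'other'",
            n_unknown,
        )
    df["chromosome"] = norm
    return df.set_index("probe_id")


def write_annotation(annotation: pd.DataFrame, path: str | PathLike) -> None:
    """Write an annotation table as TSV (columns probe_id/gene_symbol/chromosome)."""
    annotation.to_csv(path, sep="\t", index_label="probe_id")


def gene_chromosomes(annotation: pd.DataFrame) -> pd.Series:
    """Map each non-empty gene symbol to a single chromosome label.

    Symbols whose probes disagree on the chromosome get the majority label;
    exact ties go to ``"other"``.  A single warning reports how many symbols
    were ambiguous.
    """
    ann = annotation.loc[annotation["gene_symbol"] != "", ["gene_symbol", "chromosome"]]
    pairs = ann.drop_duplicates()
    per_symbol = pairs.groupby("gene_symbol", sort=True).size()
    conflicted = set(per_symbol.index[per_symbol > 1])
    simple = pairs[~pairs["gene_symbol"].isin(conflicted)]
    out: dict[str, str] = dict(zip(simple["gene_symbol"], simple["chromosome"]))
    n_conflicts = len(conflicted)
    for symbol in sorted(conflicted):
        counts = ann.loc[ann["gene_symbol"] == symbol, "chromosome"].value_counts()
        top = counts[counts == counts.iloc[0]]
        out[symbol] = top.index[0] if len(top) == 1 else "other"
    if n_conflicts:
        warnings.warn(
            f"{n_conflicts} gene symbol(s) map to multiple chromosomes; "
            "assigned the majority label (ties -> 'other')",
            stacklevel=2,
        )
    return pd.Series(out, name="chromosome", dtype=object).sort_index()


def collapse_duplicates(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> ExpressionMatrix:
    """Average duplicate probes of the same gene on the linear scale.

    Returns a matrix keyed by gene symbol, one row per distinct non-empty
    symbol, each value the arithmetic mean of that symbol's probes.
    Unannotated probes (empty symbol) are dropped; the count is logged.

    Raises
    ------
    FormatError
        If any matrix probe is absent from the annotation.
    """
    missing = matrix.values.index.difference(annotation.index)
    if len(missing):
        raise FormatError(
            f"{len(missing)} matrix probe(s) absent from annotation, "
            f"first: {missing[0]!r}"
        )
    symbols = annotation.loc[matrix.values.index, "gene_symbol"]
    keep = symbols != ""
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse_duplicates: dropped %d unannotated probe(s)", n_dropped)
    collapsed = (
        matrix.values.loc[keep.to_numpy()]
        .groupby(symbols[keep.to_numpy()], sort=True)
        .mean()
    )
    collapsed.index.name = "gene_symbol"
    return matrix.with_values(collapsed)
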