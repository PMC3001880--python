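"""Inter-array normalization, per-species averaging, and expression filters.

The analysis runs on linear-scale intensities throughout.  The inter-array
normalization surrogate is quantile normalization (the between-array step of
robust multichip averaging): after it, every column shares the identical
empirical distribution, namely the mean of the sorted columns, with ties
resolved by the midrank convention.

Filtering follows the whole-tissue comparison design: per-species mean
profiles are computed first, and a probe is kept iff its mean intensity
reaches the cut-off (default 100) in *at least one* species — i.e. probes
below the cut-off in both species are excluded as leaky background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError
from .io_annotation import ExpressionMatrix

#: Default linear-intensity cut-off separating expression from leaky background.
DEFAULT_CUTOFF = 100.0


@dataclass
class MeanProfile:
    """Per-probe (or per-gene) arithmetic mean intensity across individuals."""

    values: pd.Series
    species: str = ""
    tissue: str = ""
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise AnalysisError("mean profile contains negative values")
        if self.n_individuals < 1:
            raise AnalysisError("n_individuals must be >= 1")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all columns to share the mean-of-sorted-columns distribution.

    Ties within a column receive the average (midrank) of the reference
    values they span.  A single-column matrix is returned unchanged with a
    warning (there is nothing to normalize between).
    """
    if matrix.n_samples < 2:
        warnings.warn(
            "quantile_normalize: single-column matrix returned unchanged",
            stacklevel=2,
        )
        return matrix
    v = matrix.values.to_numpy(dtype=float)
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    grid = np.arange(v.shape[0], dtype=float)
    for j in range(v.shape[1]):
        ranks = rankdata(v[:, j], method="average")
        out[:, j] = np.interp(ranks - 1.0, grid, reference)
    normalized = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(normalized)


def average_individuals(matrix: ExpressionMatrix) -> MeanProfile:
    """Arithmetic mean across a species' individuals, per probe."""
    if matrix.n_samples < 1:
        raise AnalysisError("cannot average a matrix with no samples")
    return MeanProfile(
        values=matrix.values.mean(axis=1),
        species=matrix.species,
        tissue=matrix.tissue,
        n_individuals=matrix.n_samples,
    )


def filter_low_expression(
    profile_a: MeanProfile,
    profile_b: MeanProfile,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.Index:
    """Probes expressed above ``cutoff`` in at least one of two species.

    A probe is *excluded* only when its mean is below the cut-off in both
    species; a mean exactly equal to the cut-off counts as expressed.
    Returns the kept ids, sorted.
    """
    shared = profile_a.values.index.intersection(profile_b.values.index)
    if len(shared) == 0:
        raise AnalysisError("profiles have disjoint probe universes")
    a = profile_a.values.loc[shared]
    b = profile_b.values.loc[shared]
    kept = shared[(a >= cutoff) | (b >= cutoff)]
    return kept.sort_values()


def filter_single(profile: MeanProfile, cutoff: float = DEFAULT_CUTOFF) -> pd.Index:
    """Probes with mean intensity >= cutoff in a single profile, sorted."""
    kept = profile.values.index[profile.values >= cutoff]
    return kept.sort_values()


def subtract_fetal_expressed(
    kept_probes: pd.Index,
    annotation: pd.DataFrame,
    fetal_profile: MeanProfile,
    fetal_annotation: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.Index:
    """Remove probes whose gene is expressed in the fetal-testis profile.

    Matching is by gene symbol (case-insensitive), not probe id, because the
    fetal dataset comes from a different array platform.  Probes with an
    empty symbol cannot be matched and are retained.
    """
    fetal_kept = filter_single(fetal_profile, cutoff)
    fetal_symbols = {
        s.upper()
        for s in fetal_annotation.loc[
            fetal_annotation.index.intersection(fetal_kept), "gene_symbol"
        ]
        if s
    }
    symbols = annotation.reindex(kept_probes)["gene_symbol"].fillna("")
    mask = ~symbols.str.upper().isin(fetal_symbols) | (symbols == "")
    return kept_probes[mask.to_numpy()]
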