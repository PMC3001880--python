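"""Chromosome-class expression statistics.

Implements the per-class average expression level — AEL over all autosomes,
XEL over the X chromosome, kEL for a single autosome k — with its standard
error over probes, the two-sided Wilcoxon rank-sum contrast between classes
or species, the 22X:A representation ratio, and cell-composition
percentages.

The 22X:A statistic rests on the genomic share of the X: of ~23000 genes,
the X carries ~1000, so in a diploid XY male the number of distinct
autosomal genes is about 22-fold the number of X-linked genes.  A gene set
in which the X is represented proportionally therefore has
``22 * n_x / n_autosomal`` close to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import AnalysisError
from .io_annotation import AUTOSOME_LABELS
from .preprocess import MeanProfile

#: group sizes up to which the exact rank-sum null distribution is enumerated
EXACT_ENUMERATION_LIMIT = 20


@dataclass
class ChromClassStat:
    """Mean expression of one chromosome class (AEL when label is ``"A"``,
    XEL when ``"X"``, kEL for a single autosome label)."""

    class_label: str
    mean: float
    sem: float
    n_probes: int
    species: str = ""
    tissue: str = ""


@dataclass
class ComparisonResult:
    """Two-sided Wilcoxon rank-sum contrast between two value groups.

    ``direction`` names the group with the lower mean (``"none"`` when the
    means are equal); ``statistic`` is the rank sum of group a.
    """

    label_a: str
    label_b: str
    statistic: float
    p_value: float
    direction: str
    significant: bool
    alpha: float = 0.05


@dataclass
class XtoARatio:
    """22 * n_x / n_autosomal for a gene or probe set."""

    n_x: int
    n_autosomal: int
    ratio: float

    @property
    def rounded(self) -> float:
        """Ratio rounded half-up to one decimal, as printed in reports."""
        return math.floor(self.ratio * 10.0 + 0.5) / 10.0


def class_values(
    profile: MeanProfile,
    chromosomes: pd.Series,
    class_label: str,
    probe_subset: pd.Index | Sequence[str] | None = None,
) -> np.ndarray:
    """Mean-profile values of the probes in one chromosome class.

    ``class_label`` is either ``"A"`` (all autosomes 1..22), ``"X"``, or a
    single chromosome label.  ``probe_subset`` restricts the universe (e.g.
    to the expression-filtered set).  Y and ``"other"`` probes never enter
    class ``"A"``.
    """
    ids = profile.values.index
    if probe_subset is not None:
        ids = ids.intersection(pd.Index(probe_subset))
    chroms = chromosomes.reindex(ids)
    if class_label == "A":
        mask = chroms.isin(AUTOSOME_LABELS)
    else:
        mask = chroms == class_label
    vals = profile.values.loc[ids[mask.to_numpy().astype(bool)]].to_numpy(dtype=float)
    if vals.size == 0:
        raise AnalysisError(f"no probes in chromosome class {class_label!r}")
    return vals


def class_mean(
    profile: MeanProfile,
    chromosomes: pd.Series,
    class_label: str,
    probe_subset: pd.Index | Sequence[str] | None = None,
) -> ChromClassStat:
    """Average expression level of a chromosome class, with SEM over probes."""
    vals = class_values(profile, chromosomes, class_label, probe_subset)
    n = vals.size
    if n == 1:
        warnings.warn(
            f"class {class_label!r} has a single probe; SEM reported as 0",
            stacklevel=2,
        )
        sem = 0.0
    else:
        sem = float(np.std(vals, ddof=1) / math.sqrt(n))
    return ChromClassStat(
        class_label=class_label,
        mean=float(vals.mean()),
        sem=sem,
        n_probes=int(n),
        species=profile.species,
        tissue=profile.tissue,
    )


def _exact_rank_sum_p(doubled_ranks: np.ndarray, n_a: int, w2_obs: int) -> float:
    """Exact two-sided p by enumeration of all choices of n_a ranks.

    Works on doubled midranks (integers).  Counts the assignments whose rank
    sum deviates from the null mean at least as much as observed; equivalent
    to full enumeration of C(n, n_a) group assignments but computed by
    dynamic programming over the rank-sum distribution.
    """
    n = doubled_ranks.size
    total_sum = int(doubled_ranks.sum())
    # ways[k][s] = number of k-subsets with doubled-rank sum s
    ways = np.zeros((n_a + 1, total_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(min(n_a, 1_000_000), 0, -1):
            if r == 0:
                ways[k, :] += ways[k - 1, :]
            else:
                ways[k, r:] += ways[k - 1, :-r]
    dist = ways[n_a]
    total = math.comb(n, n_a)
    mu2 = n_a * (n + 1)  # doubled null mean of the rank sum
    dev = abs(w2_obs - mu2)
    s = np.arange(total_sum + 1)
    count = dist[np.abs(s - mu2) >= dev - 1e-9].sum()
    return float(count / total)


def wilcoxon_rank_sum(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution (enumeration over all rank
    assignments, midrank ties) when the combined size is at most
    :data:`EXACT_ENUMERATION_LIMIT`, otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = rankdata(combined, method="average")
    w = float(ranks[:n_a].sum())
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a < mean_b:
        direction = labels[0]
    elif mean_b < mean_a:
        direction = labels[1]
    else:
        direction = "none"

    if np.all(combined == combined[0]):
        p = 1.0
    elif n <= EXACT_ENUMERATION_LIMIT:
        doubled = np.rint(2.0 * ranks).astype(int)
        p = _exact_rank_sum_p(doubled, n_a, int(round(2.0 * w)))
    else:
        mu = n_a * (n + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts**3) - tie_counts).sum())
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(w - mu) - 0.5, 0.0) / math.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(z)))
    p = max(p, np.nextafter(0.0, 1.0))  # p in (0, 1]
    return ComparisonResult(
        label_a=labels[0],
        label_b=labels[1],
        statistic=w,
        p_value=p,
        direction=direction,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def x_to_a_ratio(n_x: int, n_autosomal: int) -> XtoARatio:
    """The 22X:A representation ratio ``22 * n_x / n_autosomal``."""
    if n_x < 0 or n_autosomal < 0:
        raise AnalysisError("counts must be non-negative")
    if n_autosomal == 0:
        raise AnalysisError("n_autosomal must be >= 1")
    return XtoARatio(n_x=int(n_x), n_autosomal=int(n_autosomal),
                     ratio=22.0 * n_x / n_autosomal)


def composition_percent(count: float, total: float) -> int:
    """100 * count / total, rounded half-up to the nearest integer."""
    if total <= 0:
        raise AnalysisError("total must be > 0")
    if not 0 <= count <= total:
        raise AnalysisError("count must lie in [0, total]")
    return int(math.floor(100.0 * count / total + 0.5))
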