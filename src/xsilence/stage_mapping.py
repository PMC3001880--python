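"""Spermatogenic-stage differential expression and cross-species matching.

The reference dataset contains isolated germ-cell types: B spermatogonia
(BS, premeiotic), pachytene spermatocytes (PS, meiotic prophase — where
meiotic sex chromosome inactivation acts) and round spermatids (RS,
postmeiotic haploid cells).  Genes up- or downregulated in the steps
BS->PS and PS->RS are called with the moderated t, then carried into each
target species by case-insensitive gene-symbol matching, and the matched
sets are summarised by autosomal / X-linked counts, the 22X:A ratio, and
matched-set AEL/XEL in the target species' whole-testis profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .chrom_stats import (
    ChromClassStat,
    ComparisonResult,
    XtoARatio,
    class_mean,
    class_values,
    wilcoxon_rank_sum,
    x_to_a_ratio,
)
from .errors import AnalysisError
from .io_annotation import AUTOSOME_LABELS, ExpressionMatrix
from .moderated import DEParams, call_genes, moderated_ttest
from .preprocess import MeanProfile

logger = logging.getLogger(__name__)

STEP_BS_PS = "BS-PS"
STEP_PS_RS = "PS-RS"


def _count_classes(genes: tuple[str, ...], chromosomes: pd.Series) -> tuple[int, int]:
    chroms = chromosomes.reindex(list(genes))
    n_autosomal = int(chroms.isin(AUTOSOME_LABELS).sum())
    n_x = int((chroms == "X").sum())
    return n_autosomal, n_x


@dataclass
class StageCallSet:
    """Genes called in one direction of one spermatogenic step."""

    step: str
    direction: str  # "down" or "up"
    genes: tuple[str, ...]
    n_autosomal: int
    n_x: int
    ratio: XtoARatio | None

    @classmethod
    def from_genes(
        cls, step: str, direction: str, genes: tuple[str, ...], chromosomes: pd.Series
    ) -> "StageCallSet":
        n_autosomal, n_x = _count_classes(genes, chromosomes)
        ratio = x_to_a_ratio(n_x, n_autosomal) if n_autosomal else None
        return cls(step, direction, genes, n_autosomal, n_x, ratio)


@dataclass
class MatchedSet:
    """A stage call set carried into a target species by gene symbol."""

    source: StageCallSet
    species: str
    genes: tuple[str, ...]
    n_autosomal: int
    n_x: int
    ratio: XtoARatio | None
    n_unmatched: int = 0


def call_stage_de(
    matrix_from: ExpressionMatrix,
    matrix_to: ExpressionMatrix,
    chromosomes: pd.Series,
    params: DEParams | None = None,
    step: str = STEP_BS_PS,
) -> tuple[StageCallSet, StageCallSet]:
    """Call down- and upregulated genes in the step from -> to.

    Both matrices must be keyed by the same gene ids (rows) with >= 2
    replicates each.  ``down`` means lower in ``matrix_to`` than in
    ``matrix_from``.  Returns ``(down, up)``.
    """
    params = params or DEParams()
    result = moderated_ttest(matrix_from.values, matrix_to.values, params)
    calls = call_genes(result, params)
    down = tuple(sorted(calls.index[calls == "down"]))
    up = tuple(sorted(calls.index[calls == "up"]))
    return (
        StageCallSet.from_genes(step, "down", down, chromosomes),
        StageCallSet.from_genes(step, "up", up, chromosomes),
    )


def match_by_symbol(
    callset: StageCallSet,
    target_chromosomes: pd.Series,
    species: str = "",
) -> MatchedSet:
    """Carry a call set into a target species by case-insensitive symbol.

    ``target_chromosomes`` maps the target species' gene symbols (typically
    restricted to the expressed universe) to chromosome labels; counts and
    the 22X:A ratio of the matched set use these target labels.  Unmatched
    source genes are counted and logged, not resolved.
    """
    upper_to_target: dict[str, str] = {}
    for sym in target_chromosomes.index:
        upper_to_target.setdefault(str(sym).upper(), str(sym))
    matched = sorted(
        {upper_to_target[g.upper()] for g in callset.genes if g.upper() in upper_to_target}
    )
    n_unmatched = sum(1 for g in callset.genes if g.upper() not in upper_to_target)
    if n_unmatched:
        logger.info(
            "match_by_symbol (%s %s, %s): %d of %d source gene(s) unmatched",
            callset.step, callset.direction, species or "target",
            n_unmatched, len(callset.genes),
        )
    genes = tuple(matched)
    n_autosomal, n_x = _count_classes(genes, target_chromosomes)
    ratio = x_to_a_ratio(n_x, n_autosomal) if n_autosomal else None
    return MatchedSet(
        source=callset,
        species=species,
        genes=genes,
        n_autosomal=n_autosomal,
        n_x=n_x,
        ratio=ratio,
        n_unmatched=n_unmatched,
    )


def matched_class_means(
    matched: MatchedSet,
    species_profile: MeanProfile,
    chromosomes: pd.Series,
    alpha: float = 0.05,
) -> tuple[ChromClassStat, ChromClassStat, list[ComparisonResult]]:
    """Matched-set AEL and XEL in one species' testis profile.

    Raises :class:`AnalysisError` when the matched set misses the profile
    entirely or a class is empty (e.g. an all-autosomal matched set has no
    XEL).  Returns ``(AEL, XEL, [XEL-vs-AEL contrast])``.
    """
    subset = pd.Index(matched.genes)
    if len(subset.intersection(species_profile.values.index)) == 0:
        raise AnalysisError("matched set does not intersect the expressed profile")
    ael = class_mean(species_profile, chromosomes, "A", subset)
    xel = class_mean(species_profile, chromosomes, "X", subset)
    a_vals = class_values(species_profile, chromosomes, "A", subset)
    x_vals = class_values(species_profile, chromosomes, "X", subset)
    contrast = wilcoxon_rank_sum(x_vals, a_vals, alpha=alpha, labels=("XEL", "AEL"))
    return ael, xel, [contrast]


def tabulate_stage_report(
    pairs: list[tuple[StageCallSet, MatchedSet]]
) -> pd.DataFrame:
    """Summary table of reference and matched sets per step x direction.

    Rows are ``autosomal`` / ``X-linked`` counts and the one-decimal
    ``22X:A`` ratio; columns come in (reference, matched) pairs per call
    set, mirroring the layout of a stage-matching table.
    """
    columns: dict[str, list[object]] = {}
    for callset, matched in pairs:
        base = f"{callset.step} {callset.direction}"
        columns[f"{base} reference"] = [
            callset.n_autosomal,
            callset.n_x,
            callset.ratio.rounded if callset.ratio else 0.0,
        ]
        columns[f"{base} matched"] = [
            matched.n_autosomal,
            matched.n_x,
            matched.ratio.rounded if matched.ratio else 0.0,
        ]
    return pd.DataFrame(columns, index=["autosomal", "X-linked", "22X:A"])
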