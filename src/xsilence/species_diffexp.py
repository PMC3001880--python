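"""Per-gene chimpanzee-vs-human differential expression in testis.

Applies the moderated-t machinery to the two species' whole-testis samples
(after duplicate-probe collapse and expression filtering) and summarises,
per chromosome class, the fraction of genes expressed higher, lower, or
unchanged in chimpanzee relative to human.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_annotation import AUTOSOME_LABELS, ExpressionMatrix
from .moderated import DEParams, call_genes, moderated_ttest

CALL_HIGHER = "higher"
CALL_LOWER = "lower"
CALL_UNCHANGED = "unchanged"


@dataclass
class ClassFractions:
    """Higher/lower/unchanged gene fractions for one chromosome class.

    Percentages are raw (they sum to 100 exactly); ``rounded()`` gives the
    report form, rounded half-up to integers.
    """

    class_label: str
    n_genes: int
    n_higher: int
    n_lower: int
    n_unchanged: int
    pct_higher: float
    pct_lower: float
    pct_unchanged: float

    def rounded(self) -> tuple[int, int, int]:
        r = lambda x: int(math.floor(x + 0.5))
        return r(self.pct_higher), r(self.pct_lower), r(self.pct_unchanged)


@dataclass
class DiffExpSummary:
    """Per-class higher/lower/unchanged fractions (chimpanzee vs human)."""

    classes: dict[str, ClassFractions]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            label: {
                "n_genes": cf.n_genes,
                "n_higher": cf.n_higher,
                "n_lower": cf.n_lower,
                "n_unchanged": cf.n_unchanged,
                "pct_higher": cf.pct_higher,
                "pct_lower": cf.pct_lower,
                "pct_unchanged": cf.pct_unchanged,
            }
            for label, cf in self.classes.items()
        }
        return pd.DataFrame(rows).T.rename_axis("class")


def species_de(
    chimp_matrix: ExpressionMatrix,
    human_matrix: ExpressionMatrix,
    params: DEParams | None = None,
) -> pd.Series:
    """Per-gene call in {higher, lower, unchanged}, chimpanzee vs human.

    Both matrices must be gene-collapsed with identical row index and >= 2
    samples per species.  ``higher`` means higher in chimpanzee.
    """
    params = params or DEParams()
    if chimp_matrix.n_samples < 2 or human_matrix.n_samples < 2:
        raise AnalysisError("need at least 2 samples per species")
    # log2fc of moderated_ttest is mean(b) - mean(a); put chimpanzee in b
    result = moderated_ttest(human_matrix.values, chimp_matrix.values, params)
    calls = call_genes(result, params)
    return calls.map({"up": CALL_HIGHER, "down": CALL_LOWER, "unchanged": CALL_UNCHANGED})


def fraction_by_class(
    calls: pd.Series,
    chromosomes: pd.Series,
    classes: tuple[str, ...] = ("A", "X"),
) -> DiffExpSummary:
    """Per-class percentages of higher/lower/unchanged genes."""
    chroms = chromosomes.reindex(calls.index)
    out: dict[str, ClassFractions] = {}
    for label in classes:
        if label == "A":
            mask = chroms.isin(AUTOSOME_LABELS)
        else:
            mask = chroms == label
        sub = calls[mask.to_numpy().astype(bool)]
        n = len(sub)
        if n == 0:
            raise AnalysisError(f"no genes in chromosome class {label!r}")
        n_higher = int((sub == CALL_HIGHER).sum())
        n_lower = int((sub == CALL_LOWER).sum())
        n_unchanged = n - n_higher - n_lower
        out[label] = ClassFractions(
            class_label=label,
            n_genes=n,
            n_higher=n_higher,
            n_lower=n_lower,
            n_unchanged=n_unchanged,
            pct_higher=100.0 * n_higher / n,
            pct_lower=100.0 * n_lower / n,
            pct_unchanged=100.0 * n_unchanged / n,
        )
    return DiffExpSummary(classes=out)
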