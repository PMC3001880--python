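"""End-to-end orchestration: simulate/load -> normalize -> filter -> report.

One :class:`PipelineConfig` drives the whole analysis and produces a report
bundle of TSV tables:

* class means (AEL/XEL/kEL per species) with pairwise rank-sum contrasts,
  with and without fetal-testis subtraction;
* a stage-matching table (reference and matched autosomal/X counts and
  22X:A per step x direction);
* matched-set AEL/XEL per species with contrasts;
* per-class higher/lower/unchanged species differential-expression
  fractions;
* a provenance JSON with the full configuration, seed, versions, and the
  probe/gene counts after every filter.

Outputs are written only after every stage has succeeded, so a failing
stage leaves no partial output behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .chrom_stats import ComparisonResult, class_mean, class_values, wilcoxon_rank_sum
from .errors import AnalysisError, ConfigurationError, PipelineError
from .io_annotation import (
    ExpressionMatrix,
    collapse_duplicates,
    gene_chromosomes,
    read_annotation,
    read_expression_table,
)
from .moderated import DEParams
from .preprocess import (
    DEFAULT_CUTOFF,
    MeanProfile,
    average_individuals,
    filter_low_expression,
    filter_single,
    quantile_normalize,
    subtract_fetal_expressed,
)
from .species_diffexp import fraction_by_class, species_de
from .stage_mapping import (
    STEP_BS_PS,
    STEP_PS_RS,
    MatchedSet,
    StageCallSet,
    call_stage_de,
    match_by_symbol,
    matched_class_means,
    tabulate_stage_report,
)
from .synthetic import (
    SyntheticConfig,
    generate_fetal_testis,
    generate_mouse_stage_data,
    generate_two_species_cohort,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``simulation`` (a :class:`SyntheticConfig`) or ``inputs``
    (a mapping of dataset names to TSV paths: ``chimpanzee``, ``human``,
    ``annotation``, and optionally ``fetal``/``fetal_annotation`` and
    ``mouse_bs``/``mouse_ps``/``mouse_rs``/``mouse_annotation``) must be
    given.  ``cutoff=None`` disables the expression filter (the
    no-cut-off variant).  ``seed`` overrides the simulation seed so a single
    knob controls all randomness.
    """

    simulation: SyntheticConfig | None = None
    inputs: Mapping[str, str] | None = None
    cutoff: float | None = DEFAULT_CUTOFF
    fetal_subtraction: bool = True
    classes: tuple[str, ...] = ("A", "X", "3", "6", "8")
    de_params: DEParams = field(default_factory=DEParams)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | PathLike = "xsilence_out"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of simulation / inputs must be provided"
            )
        if self.cutoff is not None and self.cutoff < 0:
            raise ConfigurationError("cutoff must be >= 0 (or None to disable)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass
class ReportBundle:
    """All tables produced by one run, plus provenance; knows how to write
    itself as TSV + JSON."""

    class_means: pd.DataFrame
    class_comparisons: pd.DataFrame
    class_means_fetal_subtracted: pd.DataFrame | None
    class_comparisons_fetal_subtracted: pd.DataFrame | None
    stage_table: pd.DataFrame | None
    matched_class_means: pd.DataFrame | None
    matched_comparisons: pd.DataFrame | None
    species_de_fractions: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | PathLike) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        tables = {
            "class_means": self.class_means,
            "class_comparisons": self.class_comparisons,
            "class_means_fetal_subtracted": self.class_means_fetal_subtracted,
            "class_comparisons_fetal_subtracted": self.class_comparisons_fetal_subtracted,
            "stage_table": self.stage_table,
            "matched_class_means": self.matched_class_means,
            "matched_comparisons": self.matched_comparisons,
            "species_de_fractions": self.species_de_fractions,
        }
        for name, table in tables.items():
            if table is None:
                continue
            paths[name] = out / f"{name}.tsv"
            table.to_csv(paths[name], sep="\t", float_format=FLOAT_FORMAT)
        paths["provenance"] = out / "provenance.json"
        paths["provenance"].write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )
        return paths


def _comparison_row(c: ComparisonResult, context: str) -> dict:
    return {
        "context": context,
        "group_a": c.label_a,
        "group_b": c.label_b,
        "rank_sum": c.statistic,
        "p_value": c.p_value,
        "direction_lower": c.direction,
        "significant": c.significant,
    }


def _class_mean_rows(
    profiles: Mapping[str, MeanProfile],
    chroms: pd.Series,
    classes: tuple[str, ...],
    subset: pd.Index,
    alpha: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class means per species plus the pairwise rank-sum contrasts."""
    rows = []
    comparisons = []
    values: dict[tuple[str, str], np.ndarray] = {}
    for species, profile in profiles.items():
        for label in classes:
            stat = class_mean(profile, chroms, label, subset)
            rows.append(
                {
                    "class": label,
                    "species": species,
                    "mean": stat.mean,
                    "sem": stat.sem,
                    "n": stat.n_probes,
                }
            )
            values[(species, label)] = class_values(profile, chroms, label, subset)
    # within-species X vs A, and cross-species contrast per class
    for species in profiles:
        if ("A" in classes) and ("X" in classes):
            c = wilcoxon_rank_sum(
                values[(species, "X")],
                values[(species, "A")],
                alpha=alpha,
                labels=(f"{species} XEL", f"{species} AEL"),
            )
            comparisons.append(_comparison_row(c, f"{species}: XEL vs AEL"))
    species_list = list(profiles)
    for i, sp_a in enumerate(species_list):
        for sp_b in species_list[i + 1 :]:
            for label in classes:
                c = wilcoxon_rank_sum(
                    values[(sp_a, label)],
                    values[(sp_b, label)],
                    alpha=alpha,
                    labels=(f"{sp_a} {label}", f"{sp_b} {label}"),
                )
                comparisons.append(
                    _comparison_row(c, f"{label}: {sp_a} vs {sp_b}")
                )
    return (
        pd.DataFrame(rows).set_index(["class", "species"]),
        pd.DataFrame(comparisons).set_index("context"),
    )


def _load_inputs(config: PipelineConfig):
    inputs = dict(config.inputs or {})
    for required in ("chimpanzee", "human", "annotation"):
        if required not in inputs:
            raise ConfigurationError(f"inputs missing required path {required!r}")
    matrices = {
        "chimpanzee": read_expression_table(
            inputs["chimpanzee"], species="chimpanzee", tissue="testis"
        ),
        "human": read_expression_table(inputs["human"], species="human", tissue="testis"),
    }
    annotation = read_annotation(inputs["annotation"])
    fetal = fetal_ann = None
    if "fetal" in inputs:
        fetal = read_expression_table(inputs["fetal"], tissue="fetal_testis")
        fetal_ann = read_annotation(inputs["fetal_annotation"])
    mouse = mouse_ann = None
    if "mouse_bs" in inputs:
        mouse = {
            stage: read_expression_table(inputs[f"mouse_{stage.lower()}"],
                                         species="mouse", tissue=stage)
            for stage in ("BS", "PS", "RS")
        }
        mouse_ann = read_annotation(inputs["mouse_annotation"])
    return matrices, annotation, fetal, fetal_ann, mouse, mouse_ann


@dataclass
class CohortClassResult:
    """XEL/AEL of one simulated two-species cohort (the class-statistics
    slice of the full pipeline, for many-seed recovery experiments)."""

    ael: dict[str, float]
    xel: dict[str, float]
    xel_vs_ael: dict[str, ComparisonResult]
    xel_cross_species: ComparisonResult
    n_expressed: int


def cohort_class_analysis(
    sim: SyntheticConfig,
    cutoff: float | None = DEFAULT_CUTOFF,
    alpha: float = 0.05,
) -> CohortClassResult:
    """Simulate one cohort and compute per-species AEL/XEL with contrasts.

    Runs exactly the pipeline's cohort path: generate -> quantile normalize
    -> collapse duplicates -> average individuals -> expression filter ->
    class statistics.
    """
    matrices, annotation, _ = generate_two_species_cohort(sim)
    profiles: dict[str, MeanProfile] = {}
    for species, matrix in matrices.items():
        collapsed = collapse_duplicates(quantile_normalize(matrix), annotation)
        profiles[species] = average_individuals(collapsed)
    gene_chroms = gene_chromosomes(annotation)
    sp = list(profiles)
    if cutoff is not None:
        expressed = filter_low_expression(profiles[sp[0]], profiles[sp[1]], cutoff)
    else:
        expressed = (
            profiles[sp[0]].values.index.intersection(profiles[sp[1]].values.index)
        ).sort_values()
    ael: dict[str, float] = {}
    xel: dict[str, float] = {}
    contrasts: dict[str, ComparisonResult] = {}
    x_values = {}
    for species, profile in profiles.items():
        a_vals = class_values(profile, gene_chroms, "A", expressed)
        x_vals = class_values(profile, gene_chroms, "X", expressed)
        ael[species] = float(a_vals.mean())
        xel[species] = float(x_vals.mean())
        contrasts[species] = wilcoxon_rank_sum(
            x_vals, a_vals, alpha=alpha, labels=("XEL", "AEL")
        )
        x_values[species] = x_vals
    cross = wilcoxon_rank_sum(
        x_values[sp[0]], x_values[sp[1]], alpha=alpha, labels=(sp[0], sp[1])
    )
    return CohortClassResult(
        ael=ael,
        xel=xel,
        xel_vs_ael=contrasts,
        xel_cross_species=cross,
        n_expressed=len(expressed),
    )


def run_full_analysis(config: PipelineConfig) -> ReportBundle:
    """Run the complete analysis and write the report bundle.

    Raises :class:`PipelineError` naming the failing stage; outputs are
    written only after all stages succeed.
    """
    stage = "setup"
    counts: dict[str, int] = {}
    try:
        stage = "inputs"
        if config.simulation is not None:
            sim = replace(config.simulation, seed=config.seed)
            matrices, annotation, _truth = generate_two_species_cohort(sim)
            mouse, mouse_ann = generate_mouse_stage_data(sim)
            fetal, fetal_ann = generate_fetal_testis(sim)
        else:
            matrices, annotation, fetal, fetal_ann, mouse, mouse_ann = _load_inputs(config)
        counts["probes"] = next(iter(matrices.values())).n_features

        stage = "preprocess"
        gene_matrices: dict[str, ExpressionMatrix] = {}
        profiles: dict[str, MeanProfile] = {}
        for species, matrix in matrices.items():
            normalized = quantile_normalize(matrix)
            collapsed = collapse_duplicates(normalized, annotation)
            gene_matrices[species] = collapsed
            profiles[species] = average_individuals(collapsed)
        gene_chroms = gene_chromosomes(annotation)
        counts["genes"] = next(iter(gene_matrices.values())).n_features

        stage = "expression filter"
        species_pair = list(profiles)
        if config.cutoff is not None:
            expressed = filter_low_expression(
                profiles[species_pair[0]], profiles[species_pair[1]], config.cutoff
            )
        else:
            expressed = (
                profiles[species_pair[0]]
                .values.index.intersection(profiles[species_pair[1]].values.index)
                .sort_values()
            )
        counts["expressed_genes"] = len(expressed)

        stage = "class statistics"
        class_means, class_comparisons = _class_mean_rows(
            profiles, gene_chroms, config.classes, expressed, config.alpha
        )

        stage = "fetal subtraction"
        class_means_fs = class_comparisons_fs = None
        if config.fetal_subtraction and fetal is not None:
            fetal_norm = quantile_normalize(fetal) if fetal.n_samples > 1 else fetal
            fetal_genes = collapse_duplicates(fetal_norm, fetal_ann)
            fetal_profile = average_individuals(fetal_genes)
            fetal_gene_ann = pd.DataFrame(
                {
                    "gene_symbol": fetal_genes.values.index,
                    "chromosome": gene_chromosomes(fetal_ann)
                    .reindex(fetal_genes.values.index)
                    .to_numpy(),
                },
                index=fetal_genes.values.index,
            )
            gene_ann = pd.DataFrame(
                {"gene_symbol": gene_chroms.index, "chromosome": gene_chroms.to_numpy()},
                index=gene_chroms.index,
            )
            remaining = subtract_fetal_expressed(
                expressed,
                gene_ann,
                fetal_profile,
                fetal_gene_ann,
                config.cutoff if config.cutoff is not None else DEFAULT_CUTOFF,
            )
            counts["expressed_genes_after_fetal_subtraction"] = len(remaining)
            class_means_fs, class_comparisons_fs = _class_mean_rows(
                profiles, gene_chroms, config.classes, remaining, config.alpha
            )

        stage = "stage mapping"
        stage_table = matched_means_table = matched_comparisons = None
        if mouse is not None:
            joint = ExpressionMatrix(
                values=pd.concat([m.values for m in mouse.values()], axis=1),
                species="mouse",
                tissue="stages",
            )
            joint = quantile_normalize(joint)
            mouse_genes = {
                stage_name: collapse_duplicates(
                    m.with_values(joint.values[m.values.columns]), mouse_ann
                )
                for stage_name, m in mouse.items()
            }
            mouse_chroms = gene_chromosomes(mouse_ann)
            callsets: list[StageCallSet] = []
            for step, (a, b) in ((STEP_BS_PS, ("BS", "PS")), (STEP_PS_RS, ("PS", "RS"))):
                down, up = call_stage_de(
                    mouse_genes[a], mouse_genes[b], mouse_chroms, config.de_params, step
                )
                callsets.extend([down, up])
            expressed_chroms = gene_chroms.loc[gene_chroms.index.intersection(expressed)]
            pairs: list[tuple[StageCallSet, MatchedSet]] = []
            matched_rows = []
            matched_comp_rows = []
            for callset in callsets:
                matched = match_by_symbol(callset, expressed_chroms, species="primate")
                pairs.append((callset, matched))
                per_species_values: dict[str, dict[str, np.ndarray]] = {}
                for species, profile in profiles.items():
                    label = f"{callset.step} {callset.direction}"
                    try:
                        ael, xel, contrasts = matched_class_means(
                            matched, profile, gene_chroms, config.alpha
                        )
                    except AnalysisError as exc:
                        logger.warning(
                            "matched class means unavailable (%s, %s): %s",
                            label, species, exc,
                        )
                        continue
                    for stat in (ael, xel):
                        matched_rows.append(
                            {
                                "set": label,
                                "species": species,
                                "class": stat.class_label,
                                "mean": stat.mean,
                                "sem": stat.sem,
                                "n": stat.n_probes,
                            }
                        )
                    for c in contrasts:
                        matched_comp_rows.append(
                            _comparison_row(c, f"{label} {species}: XEL vs AEL")
                        )
                    per_species_values[species] = {
                        "A": class_values(profile, gene_chroms, "A", pd.Index(matched.genes)),
                        "X": class_values(profile, gene_chroms, "X", pd.Index(matched.genes)),
                    }
                if len(per_species_values) == 2:
                    sp_a, sp_b = list(per_species_values)
                    for cls in ("A", "X"):
                        c = wilcoxon_rank_sum(
                            per_species_values[sp_a][cls],
                            per_species_values[sp_b][cls],
                            alpha=config.alpha,
                            labels=(f"{sp_a} {cls}", f"{sp_b} {cls}"),
                        )
                        matched_comp_rows.append(
                            _comparison_row(
                                c,
                                f"{callset.step} {callset.direction} {cls}: {sp_a} vs {sp_b}",
                            )
                        )
            stage_table = tabulate_stage_report(pairs)
            if matched_rows:
                matched_means_table = pd.DataFrame(matched_rows).set_index(
                    ["set", "species", "class"]
                )
            if matched_comp_rows:
                matched_comparisons = pd.DataFrame(matched_comp_rows).set_index("context")

        stage = "species differential expression"
        expressed_idx = pd.Index(expressed)
        chimp_expr = gene_matrices[species_pair[0]]
        human_expr = gene_matrices[species_pair[1]]
        shared = chimp_expr.values.index.intersection(expressed_idx)
        calls = species_de(
            chimp_expr.with_values(chimp_expr.values.loc[shared]),
            human_expr.with_values(human_expr.values.loc[shared]),
            config.de_params,
        )
        summary = fraction_by_class(calls, gene_chroms)
        fractions = summary.to_frame()

        stage = "provenance"
        provenance = {
            "xsilence_version": __version__,
            "seed": config.seed,
            "cutoff": config.cutoff,
            "fetal_subtraction": bool(config.fetal_subtraction and fetal is not None),
            "classes": list(config.classes),
            "alpha": config.alpha,
            "de_params": {
                "fdr_threshold": config.de_params.fdr_threshold,
                "min_abs_log2_fold_change": config.de_params.min_abs_log2_fold_change,
                "variance_shrinkage": config.de_params.variance_shrinkage,
            },
            "simulation": (
                replace(config.simulation, seed=config.seed).to_dict()
                if config.simulation is not None
                else None
            ),
            "inputs": dict(config.inputs) if config.inputs is not None else None,
            "counts": counts,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }

        bundle = ReportBundle(
            class_means=class_means,
            class_comparisons=class_comparisons,
            class_means_fetal_subtracted=class_means_fs,
            class_comparisons_fetal_subtracted=class_comparisons_fs,
            stage_table=stage_table,
            matched_class_means=matched_means_table,
            matched_comparisons=matched_comparisons,
            species_de_fractions=fractions,
            provenance=provenance,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    bundle.write(config.out_dir)
    return bundle


def render_barplots(bundle: ReportBundle, out_dir: str | PathLike) -> list[Path]:
    """Bar charts of the class-mean tables with SEM bars and significance
    asterisks.  Purely presentational; returns the files written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    panels = [("class_means", bundle.class_means, bundle.class_comparisons)]
    if bundle.class_means_fetal_subtracted is not None:
        panels.append(
            (
                "class_means_fetal_subtracted",
                bundle.class_means_fetal_subtracted,
                bundle.class_comparisons_fetal_subtracted,
            )
        )
    for name, table, comparisons in panels:
        df = table.reset_index()
        labels = [f"{r['species']} {r['class']}" for _, r in df.iterrows()]
        fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(labels)), 4))
        x = np.arange(len(labels))
        ax.bar(x, df["mean"], yerr=df["sem"], capsize=3, color="#888888")
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=45, ha="right")
        ax.set_ylabel("average expression level")
        if comparisons is not None and comparisons["significant"].any():
            note = "; ".join(
                f"* {ctx} (p={row['p_value']:.2g})"
                for ctx, row in comparisons[comparisons["significant"]].iterrows()
            )
            ax.set_title(note, fontsize=7)
        fig.tight_layout()
        path = out / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
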