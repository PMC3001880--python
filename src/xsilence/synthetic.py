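"""Synthetic two-species testis-expression cohorts with planted X silencing.

The generator emulates the statistical structure the analysis assumes:

* a shared per-gene baseline intensity drawn from a log-normal;
* four cell-type profiles per species — spermatogonia, spermatocytes,
  spermatids, somatic — where X-linked genes carry a two-fold somatic
  upregulation, are reduced to a configurable *meiotic residual* of
  baseline in spermatocytes (meiotic sex chromosome inactivation) and to a
  *postmeiotic residual* in spermatids;
* whole-testis individuals built as noisy cell-type mixtures
  ``value = (sum_c w_c * profile_c) * exp(eps)``, with log-normal
  multiplicative noise per gene and individual;
* stage-programmed genes planted up/down (default 4-fold) between the
  BS->PS and PS->RS steps; "up" program genes are testis-stage specific and
  sit at a background intensity below the expression cut-off elsewhere;
* a configurable fraction of unprogrammed genes that are adult-germline
  specific: expressed from spermatogonia onward but at background in
  somatic cells and in the fetal testis, so fetal subtraction retains them
  (the analogue of spermatocyte/spermatid-expressed genes absent from the
  fetal gonad);
* replicate reference stage datasets (BS/PS/RS, mouse-style, with its own
  residual parameters and Titlecase gene symbols to exercise
  case-insensitive matching);
* a fetal-testis profile mixing only somatic and spermatogonial cells, so
  meiotic and postmeiotic programs stay at background.

Every dataset derives from one :class:`SyntheticConfig` and its seed;
identical config + seed reproduces identical output, and the planted truth
needed for recovery tests is returned as :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_annotation import AUTOSOME_LABELS, ExpressionMatrix, write_annotation, write_expression_table
from .moderated import DEParams

CELL_TYPES: tuple[str, ...] = ("spermatogonia", "spermatocytes", "spermatids", "somatic")
STAGES: tuple[str, ...] = ("BS", "PS", "RS")
PROGRAMS: tuple[str, ...] = ("bs_ps_down", "bs_ps_up", "ps_rs_down", "ps_rs_up")

# sub-stream tags mixed with the config seed, one per independent RNG
_STREAM_GENES = 0
_STREAM_PROBES = 1
_STREAM_COHORT = 10
_STREAM_MOUSE = 20
_STREAM_FETAL = 30


def _default_gene_counts() -> dict[str, int]:
    # 500 genes per chromosome label: the X carries 1/23 of the genes, the
    # genomic proportion underlying the 22X:A statistic
    counts = {label: 500 for label in AUTOSOME_LABELS}
    counts["X"] = 500
    return counts


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-species testis experiment.

    Defaults model a small whole-testis cohort of 5 chimpanzees and 6
    humans; the cellular composition uses ~14% spermatocytes and ~48%
    spermatids of the spermatogenic epithelium, with the remainder split
    between spermatogonia and somatic cells.  Meiotic/postmeiotic residuals
    are the fraction of baseline X expression remaining in spermatocytes /
    spermatids (silencing is stronger in the chimpanzee by default).
    """

    n_genes_per_chromosome: Mapping[str, int] = field(default_factory=_default_gene_counts)
    n_individuals_per_species: Mapping[str, int] = field(
        default_factory=lambda: {"chimpanzee": 5, "human": 6}
    )
    composition: Mapping[str, float] = field(
        default_factory=lambda: {
            "spermatogonia": 0.13,
            "spermatocytes": 0.14,
            "spermatids": 0.48,
            "somatic": 0.25,
        }
    )
    x_somatic_upregulation: float = 2.0
    msci_residual: Mapping[str, float] = field(
        default_factory=lambda: {"chimpanzee": 0.15, "human": 0.45}
    )
    postmeiotic_residual: Mapping[str, float] = field(
        default_factory=lambda: {"chimpanzee": 0.15, "human": 0.45}
    )
    stage_program_sizes: Mapping[str, int] = field(
        default_factory=lambda: {p: 1000 for p in PROGRAMS}
    )
    stage_fold_change: float = 4.0
    germline_specific_fraction: float = 0.5
    background_intensity: float = 50.0
    baseline_log_mean: float = 6.0  # natural-log location of the baseline log-normal
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.2  # sd of the multiplicative log-scale noise
    mouse_msci_residual: float = 0.1
    mouse_postmeiotic_residual: float = 0.1
    mouse_replicates: int = 4
    fetal_replicates: int = 2
    duplicate_probe_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        comp_sum = sum(self.composition.values())
        if set(self.composition) != set(CELL_TYPES):
            raise ConfigurationError(
                f"composition must have exactly the cell types {CELL_TYPES}"
            )
        if abs(comp_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"composition fractions must sum to 1, got {comp_sum!r}"
            )
        if any(w < 0 for w in self.composition.values()):
            raise ConfigurationError("composition fractions must be >= 0")
        for name, mapping in (
            ("msci_residual", self.msci_residual),
            ("postmeiotic_residual", self.postmeiotic_residual),
        ):
            for sp, r in mapping.items():
                if not 0.0 <= r <= 1.0:
                    raise ConfigurationError(f"{name}[{sp!r}] must lie in [0, 1], got {r!r}")
        for name, value in (
            ("mouse_msci_residual", self.mouse_msci_residual),
            ("mouse_postmeiotic_residual", self.mouse_postmeiotic_residual),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        for name, value in (
            ("x_somatic_upregulation", self.x_somatic_upregulation),
            ("stage_fold_change", self.stage_fold_change),
            ("background_intensity", self.background_intensity),
            ("baseline_log_sd", self.baseline_log_sd),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        for name, counts in (
            ("n_genes_per_chromosome", self.n_genes_per_chromosome),
            ("n_individuals_per_species", self.n_individuals_per_species),
            ("stage_program_sizes", self.stage_program_sizes),
        ):
            for key, c in counts.items():
                if int(c) != c or c < 0 or (name != "stage_program_sizes" and c == 0):
                    raise ConfigurationError(f"{name}[{key!r}] must be a positive count")
        for name, value in (
            ("mouse_replicates", self.mouse_replicates),
            ("fetal_replicates", self.fetal_replicates),
        ):
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.duplicate_probe_fraction <= 1.0:
            raise ConfigurationError("duplicate_probe_fraction must lie in [0, 1]")
        if not 0.0 <= self.germline_specific_fraction <= 1.0:
            raise ConfigurationError("germline_specific_fraction must lie in [0, 1]")
        n_total = sum(self.n_genes_per_chromosome.values())
        if sum(self.stage_program_sizes.values()) > n_total:
            raise ConfigurationError(
                "stage_program_sizes exceed the total number of genes"
            )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.n_individuals_per_species)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "n_genes_per_chromosome",
            "n_individuals_per_species",
            "composition",
            "msci_residual",
            "postmeiotic_residual",
            "stage_program_sizes",
        ):
            d[key] = dict(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))


@dataclass
class CellTypeProfiles:
    """Noiseless per-gene linear expression of each cell type, one species."""

    species: str
    profiles: dict[str, pd.Series]  # cell type -> gene-symbol-indexed values
    genes: pd.DataFrame  # index gene_symbol; columns chromosome, baseline, program


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    programs: dict[str, tuple[str, ...]]  # program name -> gene symbols
    msci_residual: dict[str, float]
    postmeiotic_residual: dict[str, float]
    composition: dict[str, float]
    mouse_stage_means: pd.DataFrame  # noiseless BS/PS/RS means, mouse residuals
    fetal_expressed: tuple[str, ...]  # symbols >= cut-off in the noiseless fetal mix

    def expected_stage_calls(
        self, step: str, params: DEParams | None = None
    ) -> tuple[set[str], set[str]]:
        """Expected (down, up) gene sets for a step, from noiseless means.

        X genes silenced by the reference residuals are genuinely
        differential between stages, so the expectation is derived from the
        noiseless stage means at the caller's fold-change threshold: it is
        the planted programs plus silencing-induced changes.
        """
        params = params or DEParams()
        if step == "BS-PS":
            a, b = "BS", "PS"
        elif step == "PS-RS":
            a, b = "PS", "RS"
        else:
            raise ValueError(f"unknown step {step!r}")
        lfc = np.log2(self.mouse_stage_means[b] + 1.0) - np.log2(
            self.mouse_stage_means[a] + 1.0
        )
        thr = params.min_abs_log2_fold_change
        down = set(lfc.index[lfc <= -thr])
        up = set(lfc.index[lfc >= thr])
        return down, up

    def to_json(self, path: str | PathLike) -> None:
        payload = {
            "programs": {k: list(v) for k, v in self.programs.items()},
            "msci_residual": self.msci_residual,
            "postmeiotic_residual": self.postmeiotic_residual,
            "composition": self.composition,
            "mouse_stage_means": {
                stage: self.mouse_stage_means[stage].round(6).to_dict()
                for stage in self.mouse_stage_means.columns
            },
            "fetal_expressed": list(self.fetal_expressed),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _gene_table(config: SyntheticConfig) -> pd.DataFrame:
    """Shared per-gene universe: symbol, chromosome, baseline, program."""
    rng = np.random.default_rng([config.seed, _STREAM_GENES])
    chroms: list[str] = []
    order = [c for c in list(AUTOSOME_LABELS) + ["X"] if c in config.n_genes_per_chromosome]
    extra = [c for c in config.n_genes_per_chromosome if c not in order]
    for label in order + sorted(extra):
        chroms.extend([label] * int(config.n_genes_per_chromosome[label]))
    n = len(chroms)
    symbols = [f"GENE{i:05d}" for i in range(n)]
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    program = np.array(["none"] * n, dtype=object)
    sizes = [int(config.stage_program_sizes.get(p, 0)) for p in PROGRAMS]
    total = sum(sizes)
    if total:
        chosen = rng.choice(n, size=total, replace=False)
        offset = 0
        for p, size in zip(PROGRAMS, sizes):
            program[chosen[offset : offset + size]] = p
            offset += size
    # "up" program genes are stage-specific: background level outside their stage
    up_mask = np.isin(program, ("bs_ps_up", "ps_rs_up"))
    baseline = np.where(up_mask, config.background_intensity, baseline)
    # adult-germline-specific genes: drawn among unprogrammed genes; expressed
    # in germ cell types but not in somatic cells or the fetal testis
    germline = (program == "none") & (
        rng.random(n) < config.germline_specific_fraction
    )
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "baseline": baseline,
            "program": program,
            "germline": germline,
        },
        index=pd.Index(symbols, name="gene_symbol"),
    )


def _stage_values(
    genes: pd.DataFrame,
    msci_residual: float,
    postmeiotic_residual: float,
    fold: float,
) -> pd.DataFrame:
    """Noiseless per-gene expression at BS / PS / RS for given residuals."""
    base = genes["baseline"].to_numpy(dtype=float)
    prog = genes["program"].to_numpy()
    bs = base.copy()
    ps = base.copy()
    rs = base.copy()
    ps[prog == "bs_ps_down"] /= fold
    rs[prog == "bs_ps_down"] /= fold
    ps[prog == "bs_ps_up"] *= fold
    rs[prog == "bs_ps_up"] *= fold
    rs[prog == "ps_rs_down"] /= fold
    rs[prog == "ps_rs_up"] *= fold
    x = (genes["chromosome"] == "X").to_numpy()
    ps[x] *= msci_residual
    # X genes upregulated in spermatids model escape from postmeiotic
    # repression; the residual applies to the rest of the X
    escape = x & (prog == "ps_rs_up")
    rs[x & ~escape] *= postmeiotic_residual
    return pd.DataFrame({"BS": bs, "PS": ps, "RS": rs}, index=genes.index)


def _celltype_profiles_for(
    config: SyntheticConfig, species: str, genes: pd.DataFrame
) -> CellTypeProfiles:
    stages = _stage_values(
        genes,
        config.msci_residual[species],
        config.postmeiotic_residual[species],
        config.stage_fold_change,
    )
    # somatic cells express neither adult-germline-specific genes nor the
    # stage-specific "up" programs; those sit at background.  The two-fold X
    # upregulation applies to somatically expressed genes only.
    somatic = genes["baseline"].copy()
    off = genes["germline"] | genes["program"].isin(("bs_ps_up", "ps_rs_up"))
    somatic[off] = config.background_intensity
    x = (genes["chromosome"] == "X") & ~off
    somatic[x] *= config.x_somatic_upregulation
    profiles = {
        "spermatogonia": stages["BS"].rename(None),
        "spermatocytes": stages["PS"].rename(None),
        "spermatids": stages["RS"].rename(None),
        "somatic": somatic.rename(None),
    }
    return CellTypeProfiles(species=species, profiles=profiles, genes=genes)


def _fetal_noiseless(config: SyntheticConfig, genes: pd.DataFrame) -> pd.Series:
    """Noiseless fetal-testis mix: somatic + spermatogonial stem cells only.

    Fetal spermatogonial stem cells lack the adult germline program, so
    germline-specific genes sit at background in both components.
    """
    human = _celltype_profiles_for(config, _fetal_species(config), genes)
    w_som = config.composition["somatic"]
    w_spg = config.composition["spermatogonia"]
    total = w_som + w_spg
    if total <= 0:
        raise ConfigurationError("composition: somatic + spermatogonia must be > 0")
    spg_fetal = human.profiles["spermatogonia"].copy()
    spg_fetal[genes["germline"].to_numpy()] = config.background_intensity
    return (
        human.profiles["somatic"] * (w_som / total)
        + spg_fetal * (w_spg / total)
    )


def _fetal_species(config: SyntheticConfig) -> str:
    return "human" if "human" in config.species else config.species[-1]


def generate_celltype_profiles(
    config: SyntheticConfig,
) -> tuple[dict[str, CellTypeProfiles], SyntheticTruth]:
    """Per-species noiseless cell-type profiles plus the planted truth."""
    genes = _gene_table(config)
    profiles = {sp: _celltype_profiles_for(config, sp, genes) for sp in config.species}
    programs = {
        p: tuple(sorted(genes.index[genes["program"] == p])) for p in PROGRAMS
    }
    mouse_means = _stage_values(
        genes,
        config.mouse_msci_residual,
        config.mouse_postmeiotic_residual,
        config.stage_fold_change,
    )
    fetal = _fetal_noiseless(config, genes)
    truth = SyntheticTruth(
        programs=programs,
        msci_residual=dict(config.msci_residual),
        postmeiotic_residual=dict(config.postmeiotic_residual),
        composition=dict(config.composition),
        mouse_stage_means=mouse_means,
        fetal_expressed=tuple(sorted(fetal.index[fetal >= 100.0])),
    )
    return profiles, truth


def mix_tissue(
    profiles: CellTypeProfiles | Mapping[str, pd.Series],
    composition: Mapping[str, float],
    n_individuals: int,
    noise_sd: float,
    seed: int | np.random.Generator,
    species: str = "",
    tissue: str = "testis",
    sample_prefix: str | None = None,
) -> ExpressionMatrix:
    """Whole-tissue individuals as a noisy cell-type mixture.

    Each individual's per-gene value is ``(sum_c w_c * profile_c[g]) *
    exp(eps)`` with ``eps ~ Normal(0, noise_sd^2)`` drawn independently per
    gene and individual.  Runs with the same seed are bit-reproducible; the
    noise stream is consumed even at ``noise_sd = 0``.
    """
    if isinstance(profiles, CellTypeProfiles):
        if not species:
            species = profiles.species
        profiles = profiles.profiles
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd!r}")
    if set(composition) != set(profiles):
        raise ConfigurationError(
            "composition cell types do not match the profiles: "
            f"{sorted(composition)} vs {sorted(profiles)}"
        )
    if n_individuals < 1:
        raise ConfigurationError("n_individuals must be >= 1")
    index = next(iter(profiles.values())).index
    base = np.zeros(len(index), dtype=float)
    for cell_type in sorted(profiles):
        base += composition[cell_type] * profiles[cell_type].reindex(index).to_numpy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=(len(index), n_individuals)) * noise_sd
    values = base[:, None] * np.exp(eps)
    prefix = sample_prefix if sample_prefix is not None else (species or "sample")
    columns = [f"{prefix}_{i + 1}" for i in range(n_individuals)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=index, columns=columns),
        species=species,
        tissue=tissue,
    )


def _probe_table(config: SyntheticConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Primate-platform probes: shared ids for both species (the original
    two-species study hybridised both to the same human array), with a
    configurable fraction of genes carrying a duplicate probe."""
    rng = np.random.default_rng([config.seed, _STREAM_PROBES])
    n = len(genes)
    dup = rng.random(n) < config.duplicate_probe_fraction
    primary = pd.DataFrame(
        {
            "probe_id": [f"P{i:05d}_at" for i in range(n)],
            "gene_symbol": genes.index,
            "chromosome": genes["chromosome"].to_numpy(),
        }
    )
    extra = primary.loc[dup].copy()
    extra["probe_id"] = extra["probe_id"].str.replace("_at", "_x_at", regex=False)
    probes = pd.concat([primary, extra]).sort_values("probe_id")
    return probes.set_index("probe_id")


def _expand_to_probes(profile: pd.Series, probes: pd.DataFrame) -> pd.Series:
    return pd.Series(
        profile.reindex(probes["gene_symbol"]).to_numpy(), index=probes.index
    )


def generate_two_species_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, SyntheticTruth]:
    """Whole-testis cohorts for both species on a shared probe annotation.

    Returns ``(matrices, annotation, truth)``: probe-level matrices (one per
    species, 5 and 6 individuals by default), the probe annotation, and the
    planted truth.
    """
    profiles, truth = generate_celltype_profiles(config)
    genes = next(iter(profiles.values())).genes
    probes = _probe_table(config, genes)
    matrices: dict[str, ExpressionMatrix] = {}
    for k, species in enumerate(config.species):
        probe_profiles = {
            ct: _expand_to_probes(series, probes)
            for ct, series in profiles[species].profiles.items()
        }
        matrices[species] = mix_tissue(
            probe_profiles,
            config.composition,
            int(config.n_individuals_per_species[species]),
            config.noise_sd,
            seed=np.random.default_rng([config.seed, _STREAM_COHORT, k]),
            species=species,
            tissue="testis",
        )
    return matrices, probes, truth


def generate_mouse_stage_data(
    config: SyntheticConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame]:
    """Replicate reference stage datasets (BS, PS, RS), mouse-style.

    Gene symbols are Titlecase versions of the shared universe (mouse
    nomenclature), so downstream matching must be case-insensitive.  X genes
    are silenced in PS/RS by the mouse residuals; stage programs carry the
    planted fold change.
    """
    genes = _gene_table(config)
    stage_means = _stage_values(
        genes,
        config.mouse_msci_residual,
        config.mouse_postmeiotic_residual,
        config.stage_fold_change,
    )
    probe_ids = [f"M{i:05d}_at" for i in range(len(genes))]
    mouse_symbols = [s.capitalize() for s in genes.index]
    annotation = pd.DataFrame(
        {
            "gene_symbol": mouse_symbols,
            "chromosome": genes["chromosome"].to_numpy(),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    matrices: dict[str, ExpressionMatrix] = {}
    for k, stage in enumerate(STAGES):
        rng = np.random.default_rng([config.seed, _STREAM_MOUSE, k])
        base = stage_means[stage].to_numpy(dtype=float)
        eps = rng.normal(0.0, 1.0, size=(len(base), config.mouse_replicates)) * config.noise_sd
        values = base[:, None] * np.exp(eps)
        matrices[stage] = ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=annotation.index,
                columns=[f"{stage}_{i + 1}" for i in range(config.mouse_replicates)],
            ),
            species="mouse",
            tissue=stage,
        )
    return matrices, annotation


def generate_fetal_testis(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Fetal-testis profile: somatic + spermatogonia mixture only.

    Meiotic and postmeiotic program genes sit at background (below the
    default expression cut-off); the fetal platform has its own probe ids
    but shares the human gene symbols.
    """
    genes = _gene_table(config)
    fetal = _fetal_noiseless(config, genes)
    probe_ids = [f"F{i:05d}_at" for i in range(len(genes))]
    annotation = pd.DataFrame(
        {
            "gene_symbol": list(genes.index),
            "chromosome": genes["chromosome"].to_numpy(),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    rng = np.random.default_rng([config.seed, _STREAM_FETAL])
    base = fetal.to_numpy(dtype=float)
    eps = rng.normal(0.0, 1.0, size=(len(base), config.fetal_replicates)) * config.noise_sd
    values = base[:, None] * np.exp(eps)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(
            values,
            index=annotation.index,
            columns=[f"fetal_{i + 1}" for i in range(config.fetal_replicates)],
        ),
        species=_fetal_species(config),
        tissue="fetal_testis",
    )
    return matrix, annotation


def write_synthetic_bundle(config: SyntheticConfig, out_dir: str | PathLike) -> dict[str, Path]:
    """Generate every dataset and write them as TSV + truth JSON.

    Returns a name -> path map of the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, annotation, truth = generate_two_species_cohort(config)
    mouse, mouse_annotation = generate_mouse_stage_data(config)
    fetal, fetal_annotation = generate_fetal_testis(config)
    paths: dict[str, Path] = {}

    def _write_matrix(name: str, m: ExpressionMatrix) -> None:
        paths[name] = out / f"{name}.tsv"
        write_expression_table(m, paths[name])

    for species, m in matrices.items():
        _write_matrix(species, m)
    for stage, m in mouse.items():
        _write_matrix(f"mouse_{stage.lower()}", m)
    _write_matrix("fetal", fetal)
    for name, ann in (
        ("annotation", annotation),
        ("mouse_annotation", mouse_annotation),
        ("fetal_annotation", fetal_annotation),
    ):
        paths[name] = out / f"{name}.tsv"
        write_annotation(ann, paths[name])
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return paths
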