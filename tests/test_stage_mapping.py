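import numpy as np
import pandas as pd
import pytest

from conftest import make_config
from xsilence.errors import AnalysisError
from xsilence.io_annotation import ExpressionMatrix, collapse_duplicates, gene_chromosomes
from xsilence.moderated import DEParams
from xsilence.preprocess import MeanProfile
from xsilence.stage_mapping import (
    STEP_BS_PS,
    STEP_PS_RS,
    StageCallSet,
    call_stage_de,
    match_by_symbol,
    matched_class_means,
    tabulate_stage_report,
)
from xsilence.synthetic import (
    generate_celltype_profiles,
    generate_mouse_stage_data,
)


def mouse_gene_data(cfg):
    matrices, annotation = generate_mouse_stage_data(cfg)
    genes = {k: collapse_duplicates(m, annotation) for k, m in matrices.items()}
    return genes, gene_chromosomes(annotation)


class TestCallStageDE:
    def test_zero_noise_recovers_planted_truth_exactly(self):
        cfg = make_config(noise_sd=0.0)
        genes, chroms = mouse_gene_data(cfg)
        _, truth = generate_celltype_profiles(cfg)
        params = DEParams()
        for step, (a, b) in ((STEP_BS_PS, ("BS", "PS")), (STEP_PS_RS, ("PS", "RS"))):
            with pytest.warns(UserWarning, match="shrinkage disabled"):
                down, up = call_stage_de(genes[a], genes[b], chroms, params, step)
            exp_down, exp_up = truth.expected_stage_calls(step, params)
            exp_down = {g.capitalize() for g in exp_down}
            exp_up = {g.capitalize() for g in exp_up}
            assert set(down.genes) == exp_down
            assert set(up.genes) == exp_up

    def test_identical_matrices_no_calls(self):
        cfg = make_config(noise_sd=0.1)
        genes, chroms = mouse_gene_data(cfg)
        down, up = call_stage_de(genes["BS"], genes["BS"], chroms)
        assert down.genes == () and up.genes == ()

    def test_single_eightfold_gene_called_up(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(6, 1, 300)
        a = base[:, None] * np.exp(rng.normal(0, 0.1, (300, 4)))
        b = base[:, None] * np.exp(rng.normal(0, 0.1, (300, 4)))
        b[11] *= 8.0
        idx = pd.Index([f"G{i}" for i in range(300)])
        chroms = pd.Series("1", index=idx)
        down, up = call_stage_de(
            ExpressionMatrix(values=pd.DataFrame(a, index=idx)),
            ExpressionMatrix(values=pd.DataFrame(b, index=idx)),
            chroms,
        )
        assert up.genes == ("G11",)
        assert down.genes == ()


class TestMatchBySymbol:
    def target(self, mapping):
        return pd.Series(mapping, dtype=object)

    def test_case_insensitive_match(self):
        callset = StageCallSet(
            STEP_BS_PS, "down", ("Usp9x",), n_autosomal=0, n_x=1, ratio=None
        )
        matched = match_by_symbol(callset, self.target({"USP9X": "X"}))
        assert matched.genes == ("USP9X",)
        assert matched.n_x == 1
        assert matched.n_unmatched == 0

    def test_absent_symbol_counted_unmatched(self):
        callset = StageCallSet(
            STEP_BS_PS, "up", ("Abc1", "Nope2"), n_autosomal=2, n_x=0, ratio=None
        )
        matched = match_by_symbol(callset, self.target({"ABC1": "3"}))
        assert matched.genes == ("ABC1",)
        assert matched.n_unmatched == 1

    def test_intersection_counts(self):
        genes = tuple(f"g{i}" for i in range(6))
        callset = StageCallSet(
            STEP_PS_RS, "down", genes, n_autosomal=6, n_x=0, ratio=None
        )
        target = self.target({f"G{i}": "1" for i in range(4)})
        matched = match_by_symbol(callset, target)
        assert len(matched.genes) == 4
        assert matched.n_unmatched == 2
        assert matched.ratio.ratio == 0.0


class TestMatchedClassMeans:
    def profile(self, values):
        return MeanProfile(values=pd.Series(values), species="human")

    def test_hand_computed_means(self):
        prof = self.profile({"A1": 100.0, "A2": 300.0, "X1": 50.0, "X2": 150.0, "A3": 999.0})
        chroms = pd.Series({"A1": "1", "A2": "2", "A3": "3", "X1": "X", "X2": "X"})
        matched = StageCallSet(
            STEP_BS_PS, "down", ("A1", "A2", "X1", "X2"), 2, 2, None
        )
        matched = match_by_symbol(matched, chroms.drop("A3"))
        ael, xel, contrasts = matched_class_means(matched, prof, chroms)
        assert ael.mean == pytest.approx(200.0)
        assert xel.mean == pytest.approx(100.0)
        assert len(contrasts) == 1
        assert contrasts[0].label_a == "XEL"

    def test_all_autosomal_set_errors_on_xel(self):
        prof = self.profile({"A1": 10.0, "A2": 20.0})
        chroms = pd.Series({"A1": "1", "A2": "2"})
        callset = StageCallSet(STEP_BS_PS, "down", ("A1", "A2"), 2, 0, None)
        matched = match_by_symbol(callset, chroms)
        with pytest.raises(AnalysisError, match="'X'"):
            matched_class_means(matched, prof, chroms)

    def test_disjoint_profile_errors(self):
        prof = self.profile({"B1": 10.0})
        chroms = pd.Series({"A1": "1", "B1": "1"})
        callset = StageCallSet(STEP_BS_PS, "down", ("A1",), 1, 0, None)
        matched = match_by_symbol(callset, chroms[["A1"]])
        with pytest.raises(AnalysisError, match="intersect"):
            matched_class_means(matched, prof, chroms)


class TestStageReport:
    def test_published_counts_print_expected_ratio(self):
        chroms = pd.Series(
            {**{f"A{i}": "1" for i in range(5997)}, **{f"X{i}": "X" for i in range(516)}}
        )
        genes = tuple(chroms.index)
        callset = StageCallSet.from_genes(STEP_BS_PS, "down", genes, chroms)
        matched = match_by_symbol(callset, chroms)
        table = tabulate_stage_report([(callset, matched)])
        col = f"{STEP_BS_PS} down reference"
        assert table.loc["autosomal", col] == 5997
        assert table.loc["X-linked", col] == 516
        assert f"{table.loc['22X:A', col]:.1f}" == "1.9"

    def test_empty_call_set_prints_zeros(self):
        chroms = pd.Series({"G1": "1"})
        callset = StageCallSet.from_genes(STEP_PS_RS, "up", (), chroms)
        matched = match_by_symbol(callset, chroms)
        table = tabulate_stage_report([(callset, matched)])
        assert (table[f"{STEP_PS_RS} up reference"] == 0).all()

    def test_counts_equal_set_cardinalities(self):
        chroms = pd.Series({"A1": "1", "A2": "2", "X1": "X"})
        callset = StageCallSet.from_genes(STEP_BS_PS, "up", ("A1", "X1"), chroms)
        matched = match_by_symbol(callset, chroms)
        table = tabulate_stage_report([(callset, matched)])
        col = f"{STEP_BS_PS} up reference"
        assert table.loc["autosomal", col] + table.loc["X-linked", col] == len(
            callset.genes
        )


class TestRepresentationInvariant:
    def test_uniform_programs_preserve_genomic_ratio(self):
        """Without X silencing in the reference, programs planted uniformly
        over chromosomes keep the 22X:A of the combined called sets close to
        the genomic ratio of the universe (the analogue of an overall ratio
        of ~1)."""
        cfg = make_config(
            noise_sd=0.05,
            mouse_msci_residual=1.0,
            mouse_postmeiotic_residual=1.0,
            seed=3,
        )
        genes, chroms = mouse_gene_data(cfg)
        union: set[str] = set()
        for step, (a, b) in ((STEP_BS_PS, ("BS", "PS")), (STEP_PS_RS, ("PS", "RS"))):
            down, up = call_stage_de(genes[a], genes[b], chroms, step=step)
            union |= set(down.genes) | set(up.genes)
        n_x = sum(chroms[g] == "X" for g in union)
        n_a = len(union) - n_x
        universe_ratio = 22 * (chroms == "X").sum() / (chroms != "X").sum()
        assert n_a > 0
        assert 22 * n_x / n_a == pytest.approx(universe_ratio, rel=0.35)
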