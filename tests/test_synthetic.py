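import io

import numpy as np
import pandas as pd
import pytest

from conftest import make_config
from xsilence.chrom_stats import wilcoxon_rank_sum
from xsilence.errors import ConfigurationError
from xsilence.io_annotation import write_expression_table
from xsilence.preprocess import average_individuals
from xsilence.synthetic import (
    SyntheticConfig,
    generate_celltype_profiles,
    generate_fetal_testis,
    generate_mouse_stage_data,
    generate_two_species_cohort,
    mix_tissue,
)


def plain_config(**overrides):
    """No stage programs, no germline-specific genes, fixed baseline:
    isolates the silencing model."""
    defaults = dict(
        n_genes_per_chromosome={"1": 10, "X": 10},
        stage_program_sizes={},
        germline_specific_fraction=0.0,
        duplicate_probe_fraction=0.0,
        baseline_log_mean=np.log(1000.0),
        baseline_log_sd=0.0,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return make_config(**defaults)


def matrix_to_bytes(matrix) -> bytes:
    buf = io.StringIO()
    matrix.values.to_csv(buf, sep="\t", float_format="%.10g")
    return buf.getvalue().encode()


class TestConfigValidation:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="composition"):
            make_config(
                composition={
                    "spermatogonia": 0.2,
                    "spermatocytes": 0.2,
                    "spermatids": 0.2,
                    "somatic": 0.2,
                }
            )

    def test_residual_out_of_range_names_field(self):
        with pytest.raises(ConfigurationError, match="msci_residual"):
            make_config(msci_residual={"chimpanzee": 1.5, "human": 0.4})

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError, match="noise_sd"):
            make_config(noise_sd=-0.1)

    def test_zero_gene_count_rejected(self):
        with pytest.raises(ConfigurationError, match="n_genes_per_chromosome"):
            make_config(n_genes_per_chromosome={"1": 0, "X": 5})


class TestCellTypeProfiles:
    def test_no_silencing_identity(self):
        cfg = plain_config(
            msci_residual={"chimpanzee": 1.0, "human": 1.0},
            postmeiotic_residual={"chimpanzee": 1.0, "human": 1.0},
        )
        profiles, _ = generate_celltype_profiles(cfg)
        for species in cfg.species:
            p = profiles[species]
            x = p.genes["chromosome"] == "X"
            assert np.allclose(
                p.profiles["spermatocytes"][x.to_numpy()],
                p.genes.loc[x.to_numpy(), "baseline"],
            )

    def test_total_silencing_gives_zero(self):
        cfg = plain_config(msci_residual={"chimpanzee": 0.0, "human": 0.0})
        profiles, _ = generate_celltype_profiles(cfg)
        p = profiles["chimpanzee"]
        x = (p.genes["chromosome"] == "X").to_numpy()
        assert (p.profiles["spermatocytes"][x] == 0.0).all()

    def test_residual_multiplies_baseline_exactly(self):
        # 10 X genes at baseline 1000, chimp residual 0.2 -> spermatocytes 200
        cfg = plain_config(msci_residual={"chimpanzee": 0.2, "human": 0.45})
        profiles, _ = generate_celltype_profiles(cfg)
        p = profiles["chimpanzee"]
        x = (p.genes["chromosome"] == "X").to_numpy()
        assert np.allclose(p.profiles["spermatocytes"][x], 200.0)
        assert x.sum() == 10

    def test_spermatid_postmeiotic_residual(self):
        cfg = plain_config(postmeiotic_residual={"chimpanzee": 0.3, "human": 0.6})
        profiles, _ = generate_celltype_profiles(cfg)
        x = (profiles["human"].genes["chromosome"] == "X").to_numpy()
        assert np.allclose(profiles["human"].profiles["spermatids"][x], 600.0)

    def test_somatic_x_upregulation(self):
        cfg = plain_config()
        profiles, _ = generate_celltype_profiles(cfg)
        p = profiles["chimpanzee"]
        x = (p.genes["chromosome"] == "X").to_numpy()
        assert np.allclose(p.profiles["somatic"][x], 2000.0)
        assert np.allclose(p.profiles["somatic"][~x], 1000.0)

    def test_autosomal_profiles_identical_across_species(self):
        cfg = plain_config(baseline_log_sd=1.0)
        profiles, _ = generate_celltype_profiles(cfg)
        auto = (profiles["chimpanzee"].genes["chromosome"] != "X").to_numpy()
        for cell_type in ("spermatogonia", "spermatocytes", "spermatids", "somatic"):
            assert np.array_equal(
                profiles["chimpanzee"].profiles[cell_type][auto],
                profiles["human"].profiles[cell_type][auto],
            )


class TestMixTissue:
    def test_mixture_conservation_at_zero_noise(self):
        cfg = plain_config(baseline_log_sd=1.0)
        profiles, _ = generate_celltype_profiles(cfg)
        m = mix_tissue(profiles["human"], cfg.composition, 3, 0.0, seed=1)
        expected = sum(
            cfg.composition[ct] * profiles["human"].profiles[ct]
            for ct in sorted(cfg.composition)
        )
        for col in m.values:
            assert np.allclose(m.values[col], expected, rtol=0, atol=0)

    def test_single_cell_type_identity(self):
        cfg = plain_config()
        profiles, _ = generate_celltype_profiles(cfg)
        comp = {"spermatogonia": 1.0, "spermatocytes": 0.0, "spermatids": 0.0, "somatic": 0.0}
        m = mix_tissue(profiles["human"], comp, 2, 0.0, seed=0)
        for col in m.values:
            assert np.array_equal(
                m.values[col].to_numpy(),
                profiles["human"].profiles["spermatogonia"].to_numpy(),
            )

    def test_hand_computed_weighted_sum(self):
        profiles = {
            "a": pd.Series({"g": 100.0}),
            "b": pd.Series({"g": 300.0}),
        }
        m = mix_tissue(profiles, {"a": 0.5, "b": 0.5}, 1, 0.0, seed=0)
        assert m.values.iloc[0, 0] == pytest.approx(200.0)

    def test_negative_noise_rejected(self):
        profiles = {"a": pd.Series({"g": 1.0})}
        with pytest.raises(ConfigurationError, match="noise_sd"):
            mix_tissue(profiles, {"a": 1.0}, 2, -0.5, seed=0)

    def test_composition_mismatch_rejected(self):
        profiles = {"a": pd.Series({"g": 1.0})}
        with pytest.raises(ConfigurationError, match="cell types"):
            mix_tissue(profiles, {"b": 1.0}, 2, 0.0, seed=0)

    def test_seeded_runs_bit_reproducible(self):
        cfg = plain_config(baseline_log_sd=1.0)
        profiles, _ = generate_celltype_profiles(cfg)
        m1 = mix_tissue(profiles["human"], cfg.composition, 4, 0.3, seed=99)
        m2 = mix_tissue(profiles["human"], cfg.composition, 4, 0.3, seed=99)
        assert matrix_to_bytes(m1) == matrix_to_bytes(m2)


class TestTwoSpeciesCohort:
    def test_cohort_shapes_follow_config(self, small_config):
        matrices, annotation, _ = generate_two_species_cohort(small_config)
        assert matrices["chimpanzee"].n_samples == 5
        assert matrices["human"].n_samples == 6
        assert set(matrices["chimpanzee"].values.index) == set(annotation.index)

    def test_same_seed_identical_output(self, small_config):
        a = generate_two_species_cohort(small_config)[0]
        b = generate_two_species_cohort(small_config)[0]
        for sp in a:
            assert matrix_to_bytes(a[sp]) == matrix_to_bytes(b[sp])

    def test_different_seed_differs(self, small_config):
        a = generate_two_species_cohort(small_config)[0]
        b = generate_two_species_cohort(make_config(seed=1))[0]
        assert matrix_to_bytes(a["human"]) != matrix_to_bytes(b["human"])

    def test_lower_residual_lowers_x_means_only(self):
        base = dict(baseline_log_sd=1.0, noise_sd=0.0)
        strong = plain_config(
            msci_residual={"chimpanzee": 0.1, "human": 0.45},
            postmeiotic_residual={"chimpanzee": 0.1, "human": 0.45},
            **base,
        )
        weak = plain_config(
            msci_residual={"chimpanzee": 0.4, "human": 0.45},
            postmeiotic_residual={"chimpanzee": 0.4, "human": 0.45},
            **base,
        )
        means = {}
        for name, cfg in (("strong", strong), ("weak", weak)):
            matrices, annotation, _ = generate_two_species_cohort(cfg)
            prof = average_individuals(matrices["chimpanzee"])
            x_ids = annotation.index[annotation["chromosome"] == "X"]
            a_ids = annotation.index[annotation["chromosome"] != "X"]
            means[name] = (
                prof.values.loc[x_ids].mean(),
                prof.values.loc[a_ids].to_numpy(),
            )
        assert means["strong"][0] < means["weak"][0]
        assert np.allclose(means["strong"][1], means["weak"][1])

    def test_null_config_gives_no_species_contrast(self):
        """With identical residuals the cross-species X contrast should be
        non-significant in almost all seeded runs."""
        n_sig = 0
        runs = 20
        for seed in range(runs):
            cfg = make_config(
                msci_residual={"chimpanzee": 0.45, "human": 0.45},
                postmeiotic_residual={"chimpanzee": 0.45, "human": 0.45},
                seed=seed,
            )
            matrices, annotation, _ = generate_two_species_cohort(cfg)
            x_ids = annotation.index[annotation["chromosome"] == "X"]
            chimp = average_individuals(matrices["chimpanzee"]).values.loc[x_ids]
            human = average_individuals(matrices["human"]).values.loc[x_ids]
            if wilcoxon_rank_sum(chimp, human).significant:
                n_sig += 1
        assert n_sig <= 3


class TestMouseStageData:
    def test_planted_fold_change_at_zero_noise(self):
        cfg = make_config(noise_sd=0.0)
        matrices, annotation = generate_mouse_stage_data(cfg)
        _, truth = generate_celltype_profiles(cfg)
        up = truth.programs["bs_ps_up"]
        sym_to_probe = {
            s.upper(): p for p, s in annotation["gene_symbol"].items()
        }
        for gene in up[:5]:
            probe = sym_to_probe[gene.upper()]
            bs = matrices["BS"].values.loc[probe].mean()
            ps = matrices["PS"].values.loc[probe].mean()
            chrom = annotation.loc[probe, "chromosome"]
            expected = cfg.stage_fold_change * (
                cfg.mouse_msci_residual if chrom == "X" else 1.0
            )
            assert ps / bs == pytest.approx(expected)

    def test_replicate_count_as_configured(self):
        cfg = make_config(mouse_replicates=3)
        matrices, _ = generate_mouse_stage_data(cfg)
        assert all(m.n_samples == 3 for m in matrices.values())

    def test_ps_x_mean_is_residual_times_baseline(self):
        cfg = plain_config(mouse_msci_residual=0.1)
        matrices, annotation = generate_mouse_stage_data(cfg)
        x_probes = annotation.index[annotation["chromosome"] == "X"]
        assert np.allclose(matrices["PS"].values.loc[x_probes], 100.0)

    def test_mouse_symbols_titlecase(self):
        cfg = make_config()
        _, annotation = generate_mouse_stage_data(cfg)
        sym = annotation["gene_symbol"].iloc[0]
        assert sym == sym.capitalize() != sym.upper()


class TestFetalTestis:
    def test_meiotic_program_genes_below_cutoff(self):
        cfg = make_config(noise_sd=0.0)
        matrix, annotation = generate_fetal_testis(cfg)
        _, truth = generate_celltype_profiles(cfg)
        sym_to_probe = {s: p for p, s in annotation["gene_symbol"].items()}
        for gene in truth.programs["bs_ps_up"] + truth.programs["ps_rs_up"]:
            assert (matrix.values.loc[sym_to_probe[gene]] < 100.0).all()

    def test_somatic_housekeeping_gene_expressed(self):
        cfg = plain_config(fetal_replicates=2)
        matrix, annotation = generate_fetal_testis(cfg)
        auto = annotation.index[annotation["chromosome"] == "1"]
        # unprogrammed autosomal genes at baseline 1000 stay above cut-off
        assert (matrix.values.loc[auto] >= 100.0).all().all()

    def test_truth_fetal_set_matches_cutoff_at_zero_noise(self):
        cfg = make_config(noise_sd=0.0)
        matrix, annotation = generate_fetal_testis(cfg)
        _, truth = generate_celltype_profiles(cfg)
        prof = average_individuals(matrix)
        expressed_probes = prof.values.index[prof.values >= 100.0]
        expressed_symbols = set(annotation.loc[expressed_probes, "gene_symbol"])
        assert expressed_symbols == set(truth.fetal_expressed)
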