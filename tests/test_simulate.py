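"""Synthetic cohort generator: sequences, copula, counts, export."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutburden import codon, simulate
from mutburden.simulate import (
    BackgroundSpec,
    DriverSpec,
    SimulationConfig,
    export_cohort,
    generate_cds,
    generate_cohort,
)


class TestGenerateCds:
    def test_minimal_two_codons(self, rng):
        cds = generate_cds(2, (0.25, 0.25, 0.25, 0.25), rng)
        assert cds.length_nt == 6
        assert cds.sequence.startswith("ATG")
        assert cds.sequence[3:] in {"TAA", "TAG", "TGA"}

    def test_no_internal_stops(self, rng):
        for _ in range(20):
            cds = generate_cds(50, (0.1, 0.2, 0.3, 0.4), rng)
            internal = cds.codons()[1:-1]
            assert not set(internal) & codon.STOP_CODONS

    def test_composition_approaches_stop_conditioned_target(self):
        # oracle: expected base fractions of codons sampled base-wise from
        # the target, conditioned on not being a stop codon
        rng = np.random.default_rng(8)
        target = np.array([0.25, 0.25, 0.25, 0.25])
        probs, base_counts = [], []
        for c in codon.ALL_CODONS:
            if c in codon.STOP_CODONS:
                continue
            probs.append(np.prod([target["ACGT".index(b)] for b in c]))
            base_counts.append([c.count(b) for b in "ACGT"])
        probs = np.array(probs) / np.sum(probs)
        expected = (probs[:, None] * np.array(base_counts)).sum(axis=0) / 3
        cds = generate_cds(10_000, target, rng)
        comp = codon.composition_stats(cds)
        realized = np.array([comp.p_a, comp.p_c, comp.p_g, comp.p_t])
        assert np.abs(realized - expected).max() < 0.01

    def test_zero_probability_base_absent_from_body(self, rng):
        cds = generate_cds(200, (0.4, 0.0, 0.3, 0.3), rng)
        body = cds.sequence[3:-3]  # exclude fixed ATG start and stop codon
        assert "C" not in body

    def test_too_few_codons_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_cds(1, (0.25, 0.25, 0.25, 0.25), rng)


class TestConfig:
    def test_seed_determinism(self):
        c1 = generate_cohort(SimulationConfig.feature_only(seed=3, n_genes=150))
        c2 = generate_cohort(SimulationConfig.feature_only(seed=3, n_genes=150))
        pd.testing.assert_frame_equal(c1.features, c2.features)
        pd.testing.assert_frame_equal(c1.counts.counts, c2.counts.counts)

    def test_invalid_correlation_rejected(self):
        bad = np.full((7, 7), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99  # wildly non-PSD
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, copula_corr=bad)

    def test_hash_changes_iff_config_changes(self):
        a = SimulationConfig.feature_only(seed=1, n_genes=100)
        b = SimulationConfig.feature_only(seed=1, n_genes=100)
        c = SimulationConfig.feature_only(seed=2, n_genes=100)
        assert a.content_hash() == b.content_hash()
        assert a.content_hash() != c.content_hash()


class TestCopula:
    def test_zero_offdiagonal_gives_uncorrelated_covariates(self):
        config = SimulationConfig.feature_only(seed=21, n_genes=5000)
        config.copula_corr = np.eye(7)
        cohort = generate_cohort(config)
        X = cohort.features
        pairs = [
            ("log_mean_expression", "replication_time"),
            ("replication_time", "chromatin_accessibility"),
            ("log_mean_expression", "chromatin_accessibility"),
        ]
        for a, b in pairs:
            rho = stats.spearmanr(X[a], X[b]).statistic
            assert abs(rho) < 0.05

    def test_configured_negative_correlation_recovered(self):
        config = SimulationConfig.feature_only(seed=22, n_genes=5000)
        corr = np.eye(7)
        corr[0, 1] = corr[1, 0] = -0.3  # log length vs expression
        config.copula_corr = corr
        cohort = generate_cohort(config)
        rho = stats.spearmanr(
            np.log(cohort.features["cds_length"]),
            cohort.features["log_mean_expression"],
        ).statistic
        assert rho == pytest.approx(-0.3, abs=0.05)


class TestCounts:
    def test_intercept_only_poisson_mean(self):
        config = SimulationConfig.feature_only(seed=9, n_genes=5000)
        for t in simulate.MUTATION_TYPES:
            config.backgrounds[t] = BackgroundSpec(
                mean_count=10.0, raw_beta={}, raw_intercept=10.0
            )
        cohort = generate_cohort(config)
        means = cohort.counts.counts.mean()
        for col in ("n_missense", "n_nonsense", "n_fs", "n_silent"):
            assert 9.7 <= means[col] <= 10.3

    def test_driver_injection_is_type_specific(self, tiny_default_cohort):
        cohort = tiny_default_cohort
        truth = cohort.truth_drivers
        og = truth.index[truth["kind"] == "OG"]
        lam = cohort.truth_lambda
        h = cohort.truth_latent.to_numpy()
        bg = {
            t: pd.Series(
                simulate._lambda_for_type(cohort.config.backgrounds[t], cohort.features, h)[0],
                index=cohort.features.index,
            )
            for t in ("missense", "nonsense", "frameshift")
        }
        # OG drivers carry a missense excess but background nonsense/FS rates
        delta = cohort.config.drivers.delta_missense
        for g in og:
            assert lam.loc[g, "lambda_nonsense"] == pytest.approx(bg["nonsense"][g])
            assert lam.loc[g, "lambda_frameshift"] == pytest.approx(bg["frameshift"][g])
            assert lam.loc[g, "lambda_missense"] == pytest.approx(
                (1 + delta) * bg["missense"][g]
            )

    def test_silent_counts_never_boosted(self, tiny_default_cohort):
        cohort = tiny_default_cohort
        spec = cohort.config.backgrounds["silent"]
        lam, _ = simulate._lambda_for_type(
            spec, cohort.features, cohort.truth_latent.to_numpy()
        )
        assert np.allclose(cohort.truth_lambda["lambda_silent"].to_numpy(), lam)

    def test_truth_beta_reproduces_lambda(self, small_feature_cohort):
        # raw-scale generating coefficients must rebuild lambda exactly
        cohort = small_feature_cohort
        X = cohort.features
        for t in ("missense", "nonsense", "frameshift"):
            beta = cohort.truth_beta[t]
            lam = np.full(len(X), beta["intercept"])
            for col, b in beta.items():
                if col != "intercept" and b != 0.0:
                    lam = lam + b * X[col].to_numpy()
            assert np.allclose(
                lam.clip(0), cohort.truth_lambda[f"lambda_{t}"].to_numpy(), atol=1e-8
            )


class TestExport:
    @pytest.fixture(scope="class")
    def exported(self, tmp_path_factory):
        config = SimulationConfig.default(seed=13, n_genes=120)
        config.drivers = DriverSpec(n_ts=2, n_og=2)
        cohort = generate_cohort(config)
        out = tmp_path_factory.mktemp("cohort")
        paths = export_cohort(cohort, out)
        return cohort, out, paths

    def test_roundtrip_feature_matrix_identical(self, exported):
        from mutburden import covariates, mutations

        cohort, out, paths = exported
        genes = codon.read_cds_fasta(paths["fasta"])
        seq_feats = codon.sequence_features(genes.values())
        records = mutations.filter_records(mutations.read_mutation_tsv(paths["mutations"]))
        table = mutations.count_by_gene(records, genes.keys())
        cov = pd.read_csv(paths["covariates"], sep="\t", index_col=0)
        expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        intervals = covariates.read_gene_intervals(paths["genes_bed"])
        track = covariates.ProbeTrack.from_bed(paths["reptime_bed"])
        fm = covariates.build_feature_matrix(
            seq_feats,
            cov["n_orthologs"],
            cov["n_unique_snps"],
            expr,
            covariates.assign_track_to_genes(track, intervals),
            cov["chromatin_accessibility"],
            mutsig=cov[["mutsig_expr", "mutsig_hic", "mutsig_reptime"]],
            silent_counts=table.counts["n_silent"],
        )
        pd.testing.assert_frame_equal(fm.scoring, cohort.features, check_names=False)
        pd.testing.assert_frame_equal(table.counts, cohort.counts.counts)

    def test_contaminants_present_but_filtered(self, exported):
        from mutburden import mutations

        _, _, paths = exported
        raw = mutations.read_mutation_tsv(paths["mutations"])
        kept = mutations.filter_records(raw)
        assert len(kept) < len(raw)  # contaminant admixture exists

    def test_truth_files_separate_from_inputs(self, exported):
        _, out, paths = exported
        input_files = {paths[k].name for k in
                       ("fasta", "mutations", "expression", "covariates",
                        "genes_bed", "reptime_bed")}
        truth_files = {p.name for p in out.glob("truth_*")}
        assert truth_files == {
            "truth_lambda.tsv", "truth_beta.tsv", "truth_drivers.tsv", "truth_latent.tsv"
        }
        assert not input_files & truth_files
        assert not any(f.startswith("truth") for f in input_files)

    def test_manifest_records_seed_and_hash(self, exported):
        cohort, _, paths = exported
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 13
        assert manifest["config_hash"] == cohort.config.content_hash()
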