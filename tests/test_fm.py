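"""Foundation model: tokenization, invariances, training, fine-tuning, probes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multiscreen.errors import ConfigError, ValidationError
from multiscreen.fm import (
    FMConfig,
    FMModel,
    finetune,
    fourier_embed,
    joint_consistency,
    pathway_score,
    probe_mutation,
    probe_pathway,
    train_fm,
)


@pytest.fixture(scope="module")
def desk_model():
    return FMModel(FMConfig.desk(seed=0), drug_vocab=[f"d{i}" for i in range(10)])


class TestConfig:
    def test_hidden_must_be_three_subembeddings(self):
        with pytest.raises(ConfigError):
            FMConfig(hidden=256, sub_embedding=128)

    def test_heads_must_divide_hidden(self):
        with pytest.raises(ConfigError):
            FMConfig(n_heads=7)

    def test_paper_preset_dimensions(self):
        cfg = FMConfig.paper()
        assert cfg.hidden == 384 and cfg.sub_embedding == 128
        assert cfg.n_blocks == 8 and cfg.intermediate == 512 and cfg.n_heads == 8


class TestFourier:
    def test_output_length_matches_subembedding(self, desk_model):
        out = fourier_embed([0.5], desk_model.dose_fourier)
        assert out.shape == (1, desk_model.cfg.sub_embedding)

    def test_paper_width_is_128(self):
        model = FMModel(FMConfig.paper(), drug_vocab=["d"])
        assert fourier_embed([1.0], model.dose_fourier).shape == (1, 128)

    def test_equal_inputs_identical_embeddings(self, desk_model):
        out = fourier_embed([0.3, 0.3], desk_model.dose_fourier)
        assert np.array_equal(out.data[0], out.data[1])

    def test_distinct_doses_differ(self, desk_model):
        out = fourier_embed([0.0, 1.5], desk_model.dose_fourier)
        assert np.linalg.norm(out.data[0] - out.data[1]) > 0

    def test_non_finite_errors(self, desk_model):
        with pytest.raises(ValidationError):
            fourier_embed([np.nan], desk_model.dose_fourier)


class TestTokenize:
    def test_token_width_is_three_concatenated_subembeddings(self):
        model = FMModel(FMConfig.paper(), drug_vocab=["a", "b"])
        ctx, qry = model.tokenize([("a", 0.0, 1.0)], [("b", 1.0)])
        assert ctx.shape == (1, 384) and qry.shape == (1, 384)

    def test_identical_queries_identical_tokens(self, desk_model):
        _, qry = desk_model.tokenize([("d0", 0.0, 1.0)], [("d1", 0.5), ("d1", 0.5)])
        assert np.array_equal(qry.data[0], qry.data[1])

    def test_unseen_drug_maps_to_oov_with_warning(self, desk_model):
        with pytest.warns(UserWarning, match="OOV"):
            ctx, _ = desk_model.tokenize([("martian_drug", 0.0, 1.0)], [("d0", 0.5)])
        oov = desk_model.params["drug_emb"].data[-1]
        assert np.array_equal(ctx.data[0, : desk_model.cfg.sub_embedding], oov)


class TestPredict:
    def _ctx(self, rng, model, n):
        drugs = [f"d{rng.integers(10)}" for _ in range(n)]
        return [(d, rng.uniform(-2, 2), rng.uniform(0, 1)) for d in drugs]

    def test_context_permutation_invariance(self, desk_model):
        rng = np.random.default_rng(0)
        ctx = self._ctx(rng, desk_model, 12)
        qry = [("d3", 0.2), ("d5", -0.7)]
        a = desk_model.predict_query(ctx, qry)
        b = desk_model.predict_query(list(reversed(ctx)), qry)
        assert np.allclose(a, b, atol=1e-6)

    def test_query_permutation_invariance(self, desk_model):
        rng = np.random.default_rng(1)
        ctx = self._ctx(rng, desk_model, 8)
        qry = [("d1", 0.1), ("d2", 0.4), ("d3", -0.3)]
        a = desk_model.predict_query(ctx, qry)
        b = desk_model.predict_query(ctx, qry[::-1])
        assert np.allclose(a, b[::-1], atol=1e-6)

    def test_output_count_matches_queries(self, desk_model):
        rng = np.random.default_rng(2)
        ctx = self._ctx(rng, desk_model, 5)
        assert len(desk_model.predict_query(ctx, [("d0", 0.0)] * 7)) == 7
        assert len(desk_model.predict_query(ctx, [])) == 0

    def test_empty_context_prior_like_with_warning(self, desk_model):
        with pytest.warns(UserWarning, match="prior"):
            out = desk_model.predict_query([], [("d0", 0.0)])
        assert out.shape == (1,) and np.all((out >= 0) & (out <= 2))

    def test_outputs_clipped_to_interface_range(self, desk_model):
        rng = np.random.default_rng(3)
        out = desk_model.predict_query(self._ctx(rng, desk_model, 6), [("d0", 0.0)] * 5)
        assert np.all((out >= 0) & (out <= 2))


class TestEmbedding:
    def test_length_is_hidden_size(self, desk_model):
        emb = desk_model.extract_sample_embedding([("d0", 0.0, 1.0), ("d1", 1.0, 0.5)])
        assert emb.shape == (desk_model.cfg.hidden,)

    def test_paper_embedding_is_384(self):
        model = FMModel(FMConfig.paper(), drug_vocab=["a"])
        assert model.extract_sample_embedding([("a", 0.0, 1.0)]).shape == (384,)

    def test_permutation_invariant(self, desk_model):
        ctx = [("d0", 0.0, 1.0), ("d1", 1.0, 0.5), ("d2", -1.0, 0.9)]
        a = desk_model.extract_sample_embedding(ctx)
        b = desk_model.extract_sample_embedding(ctx[::-1])
        assert np.allclose(a, b, atol=1e-6)

    def test_identical_contexts_identical_embeddings(self, desk_model):
        ctx = [("d0", 0.0, 1.0)]
        assert np.array_equal(
            desk_model.extract_sample_embedding(ctx),
            desk_model.extract_sample_embedding(list(ctx)),
        )

    def test_empty_context_errors(self, desk_model):
        with pytest.raises(ValidationError):
            desk_model.extract_sample_embedding([])


class TestTraining:
    def test_loss_decreases_and_heldout_excluded(self, small_screen):
        _, ds, _ = small_screen
        cfg = FMConfig.desk(seed=0, n_steps=60, batch_episodes=4)
        model = train_fm(ds, cfg, exclude_studies=["study_2"])
        assert np.mean(model.loss_trace[-10:]) < np.mean(model.loss_trace[:10])
        assert "study_2" not in model.trained_studies

    def test_same_seed_identical_weights(self, small_screen):
        _, ds, _ = small_screen
        cfg = FMConfig.desk(seed=3, n_steps=10, batch_episodes=2)
        a = train_fm(ds, cfg)
        b = train_fm(ds, cfg)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_save_load_round_trip(self, tmp_path, small_screen):
        _, ds, _ = small_screen
        model = train_fm(ds, FMConfig.desk(seed=1, n_steps=5, batch_episodes=2))
        model.save(tmp_path / "fm")
        back = FMModel.load(tmp_path / "fm")
        ctx = [("drug_000", 0.0, 1.0), ("drug_001", 0.5, 0.7)]
        qry = [("drug_002", 0.1)]
        assert np.array_equal(model.predict_query(ctx, qry), back.predict_query(ctx, qry))


class TestFinetune:
    def test_zero_epochs_identity(self, desk_model):
        few = [("d0", 0.0, 1.0), ("d1", 1.0, 0.4)]
        ft = finetune(desk_model, few, n_epochs=0)
        qry = [("d2", 0.0)]
        assert np.array_equal(desk_model.predict_query(few, qry), ft.predict_query(few, qry))

    def test_original_model_unchanged(self, desk_model):
        few = [("d0", 0.0, 1.0), ("d1", 1.0, 0.4), ("d2", -1.0, 0.8)]
        before = {k: t.data.copy() for k, t in desk_model.params.items()}
        finetune(desk_model, few, n_epochs=3, seed=0)
        for k in before:
            assert np.array_equal(before[k], desk_model.params[k].data)

    def test_empty_fewshot_errors(self, desk_model):
        with pytest.raises(ValidationError):
            finetune(desk_model, [])

    def test_finetune_adapts_to_shifted_distribution(self, trained_fm, default_screen):
        # a sample with viabilities shifted far from training distribution
        _, ds, _ = default_screen
        from multiscreen.fm import _sample_measurements

        per = _sample_measurements(ds.subset_studies(["study_0"]))
        sid = sorted(per)[0]
        drugs, doses, viab = per[sid]
        shifted = np.clip(viab * 0.3, 0, 2)  # violates training distribution
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(drugs))
        tr, te = idx[:40], idx[40:80]
        few = list(zip(drugs[tr], doses[tr], shifted[tr]))
        qry = list(zip(drugs[te], doses[te]))
        base_mse = np.mean((trained_fm.predict_query(few, qry) - shifted[te]) ** 2)
        ft = finetune(trained_fm, few, n_epochs=30, lr=1e-3, seed=0)
        ft_mse = np.mean((ft.predict_query(few, qry) - shifted[te]) ** 2)
        assert ft_mse < base_mse


class TestProbes:
    def test_separable_mutation_high_auroc(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=(60, 8)) + 3.0 * y[:, None]
        res = probe_mutation(x, y, seed=0, target="G")
        assert res.value >= 0.95 and not res.skipped

    def test_random_labels_auroc_near_half(self):
        rng = np.random.default_rng(1)
        vals = []
        for seed in range(5):
            y = rng.permutation(np.repeat([0, 1], 30))
            x = rng.normal(size=(60, 8))
            vals.append(probe_mutation(x, y, seed=seed).value)
        assert abs(np.mean(vals) - 0.5) < 0.12

    def test_single_class_skipped(self):
        res = probe_mutation(np.zeros((20, 4)), np.zeros(20, int))
        assert res.skipped

    def test_linear_pathway_score_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 8))
        w = rng.normal(size=8)
        res = probe_pathway(x, x @ w, seed=0, target="P")
        assert res.value >= 0.95

    def test_permuted_scores_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 8))
        y = rng.permutation(x @ rng.normal(size=8))
        assert abs(probe_pathway(x, y, seed=0).value) < 0.3

    def test_constant_score_skipped(self):
        assert probe_pathway(np.zeros((20, 4)), np.ones(20)).skipped


class TestPathwayScore:
    def _expr(self, data, genes, samples):
        return pd.DataFrame(data, index=genes, columns=samples)

    def test_single_gene_with_leniency_equals_standardized_expression(self):
        rng = np.random.default_rng(0)
        expr = self._expr(np.exp(rng.normal(3, 1, (3, 20))), ["g1", "g2", "g3"],
                          [f"s{i}" for i in range(20)])
        score = pathway_score(expr, ["g1"], allow_single=True)
        x = expr.to_numpy()
        norm = x / x.sum(axis=0) * np.median(x.sum(axis=0))
        logx = np.log1p(norm)
        expected = (logx[0] - logx[0].mean()) / logx[0].std()
        assert np.allclose(np.abs(score), np.abs(expected), atol=1e-9)

    def test_duplicated_gene_rows_do_not_change_score(self):
        rng = np.random.default_rng(1)
        expr = self._expr(np.exp(rng.normal(3, 1, (4, 15))), ["a", "b", "c", "d"],
                          [f"s{i}" for i in range(15)])
        dup = pd.concat([expr, expr.loc[["a"]]])
        assert np.allclose(
            pathway_score(expr, ["a", "b"]), pathway_score(dup, ["a", "b", "a"])
        )

    def test_score_variance_is_top_eigenvalue_of_member_structure(self):
        rng = np.random.default_rng(2)
        n = 400
        expr = self._expr(np.exp(rng.normal(3, 0.5, (3, n))), ["a", "b", "c"],
                          [f"s{i}" for i in range(n)])
        score = pathway_score(expr, ["a", "b", "c"])
        x = expr.to_numpy()
        norm = x / x.sum(axis=0) * np.median(x.sum(axis=0))
        logx = np.log1p(norm)
        zstd = (logx - logx.mean(axis=1, keepdims=True)) / logx.std(axis=1, keepdims=True)
        eig = np.linalg.eigvalsh(zstd @ zstd.T / 1.0)[-1]
        assert np.var(score) * n / eig == pytest.approx(1.0, rel=1e-6)

    def test_too_few_members_errors(self):
        expr = self._expr(np.ones((2, 5)) + np.arange(5), ["a", "b"], list("vwxyz"))
        with pytest.raises(ValidationError):
            pathway_score(expr, ["a"])


class TestJointConsistency:
    def test_identical_repeats_fisher_closed_form(self):
        rng = np.random.default_rng(0)
        mutant = np.repeat([True, False], 15)
        values = rng.normal(size=30) + 1.0 * mutant
        p_single = stats.mannwhitneyu(values[mutant], values[~mutant],
                                      alternative="greater").pvalue
        res = joint_consistency({"r": [values] * 5}, mutant, {"r": "greater"})
        expected = stats.chi2.sf(-2 * 5 * np.log(p_single), 10)
        assert res["r"]["p_combined"] == pytest.approx(expected)

    def test_planted_coupling_significant(self):
        rng = np.random.default_rng(1)
        mutant = np.repeat([True, False], 20)
        readouts = {
            "mutation_logit": [rng.normal(size=40) + 2 * mutant for _ in range(5)],
            "pathway_score": [rng.normal(size=40) + 1.5 * mutant for _ in range(5)],
            "predicted_auc": [rng.normal(size=40) - 1.5 * mutant for _ in range(5)],
        }
        res = joint_consistency(
            readouts, mutant,
            {"mutation_logit": "greater", "pathway_score": "greater",
             "predicted_auc": "less"},
        )
        assert all(v["p_combined"] < 0.05 for v in res.values())

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            joint_consistency({"r": [np.ones(5)]}, np.ones(5, bool), {})
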