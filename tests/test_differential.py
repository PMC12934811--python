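"""Differential-sensitivity statistics: BH, permutation, tissue/met/cell-line
comparisons and k-NN embedding analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multiscreen.differential import (
    bh_adjust,
    cellline_vs_exvivo,
    favoring_share,
    fisher_method,
    knn_label_analysis,
    met_vs_primary_auc,
    met_vs_primary_zdiff,
    paired_group_ranking,
    permutation_test,
    tissue_vs_rest,
)
from multiscreen.errors import ConfigError, ValidationError
from multiscreen.metrics import CurveSummary
from multiscreen.screen_data import SampleAnnotation


def brute_force_bh(p):
    """Independent step-up oracle."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q


class TestBH:
    def test_hand_stepped_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_empty_is_empty(self):
        assert len(bh_adjust([])) == 0

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestPermutation:
    def test_extreme_separation_hits_add_one_floor(self):
        a = np.arange(12) + 100.0
        b = np.arange(12) - 100.0
        p, _ = permutation_test(a, b, B=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            p, _ = permutation_test(a, b, B=199, seed=i)
            rejections += p <= 0.05
        # binomial tolerance around 0.05
        assert rejections <= stats.binom.ppf(0.999, n_rep, 0.05) + 1

    def test_zero_permutations_errors(self):
        with pytest.raises(ConfigError):
            permutation_test([1, 2, 3], [4, 5, 6], B=0)

    def test_small_group_errors(self):
        with pytest.raises(ValidationError):
            permutation_test([1.0], [2.0, 3.0, 4.0], B=99)

    def test_seed_determinism(self):
        a = np.random.default_rng(0).normal(size=6)
        b = np.random.default_rng(1).normal(size=6)
        assert permutation_test(a, b, B=299, seed=5) == permutation_test(a, b, B=299, seed=5)


class TestFisher:
    def test_half_half_closed_form(self):
        p, chi2 = fisher_method([0.5, 0.5])
        assert chi2 == pytest.approx(-2 * np.log(0.25))
        assert p == pytest.approx(stats.chi2.sf(2.77, 4), abs=0.01)
        assert p == pytest.approx(0.597, abs=0.005)

    def test_identical_repeats_closed_form(self):
        k, p0 = 5, 0.03
        p, chi2 = fisher_method([p0] * k)
        assert p == pytest.approx(stats.chi2.sf(-2 * k * np.log(p0), 2 * k))


def _annotations(n_per_tissue, tissues, mets=0, modality="PDC"):
    out = {}
    i = 0
    for t in tissues:
        for _ in range(n_per_tissue):
            is_met = i % n_per_tissue < mets
            out[f"s{i}"] = SampleAnnotation(
                sample_id=f"s{i}", study_id="st", oncotree_code=f"D_{t}",
                primary_site=t, is_metastasis=is_met,
                metastatic_site=t if is_met else None, model_type=modality,
            )
            i += 1
    return out


class TestTissueVsRest:
    def _z_frame(self, samples, n_drugs, shift_fn, rng):
        rows = []
        for sid, ann in samples.items():
            for j in range(n_drugs):
                rows.append(
                    {"sample_id": sid, "drug_id": f"d{j}",
                     "z": rng.normal() + shift_fn(ann, j), "provenance": "imputed"}
                )
        return pd.DataFrame(rows)

    def test_planted_shift_recovered_as_sensitive_hit(self):
        samples = _annotations(8, ["lung", "liver", "skin", "bone"])
        rng = np.random.default_rng(0)
        z = self._z_frame(
            samples, 12,
            lambda ann, j: 2.0 if (ann.primary_site == "lung" and j == 3) else 0.0,
            rng,
        )
        hits = tissue_vs_rest(z, samples, min_n=3, fdr=0.1)
        row = hits[(hits["unit"] == "d3") & (hits["stratum"] == "lung")]
        assert bool(row["hit"].iloc[0]) and row["direction"].iloc[0] == "sensitive"

    def test_null_data_controls_fdr(self):
        total_hits, total_tests = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            samples = _annotations(6, ["lung", "liver", "skin", "bone"])
            z = self._z_frame(samples, 15, lambda a, j: 0.0, rng)
            hits = tissue_vs_rest(z, samples, min_n=3, fdr=0.1)
            total_hits += hits["hit"].sum()
            total_tests += len(hits)
        # under the full null BH keeps the family-wise hit rate near alpha
        assert total_hits <= 0.02 * total_tests + 3

    def test_small_tissue_excluded(self):
        samples = _annotations(5, ["lung", "liver"])
        samples["tiny"] = SampleAnnotation(sample_id="tiny", study_id="st",
                                           primary_site="bone", oncotree_code="OS")
        rng = np.random.default_rng(0)
        z = self._z_frame(samples, 6, lambda a, j: 0.0, rng)
        hits = tissue_vs_rest(z, samples, min_n=3)
        assert "bone" not in set(hits["stratum"])

    def test_metastatic_samples_excluded(self):
        samples = _annotations(6, ["lung", "liver"], mets=6)  # lung all met
        rng = np.random.default_rng(0)
        z = self._z_frame(samples, 6, lambda a, j: 0.0, rng)
        with pytest.warns(UserWarning):
            hits = tissue_vs_rest(z, samples, min_n=3)
        assert hits.empty


class TestMetVsPrimary:
    def _summaries(self, samples, auc_fn, n_drugs=10, rng=None):
        rng = rng or np.random.default_rng(0)
        return [
            CurveSummary(sample_id=sid, drug_id=f"d{j}", auc=auc_fn(ann, j, rng))
            for sid, ann in samples.items() for j in range(n_drugs)
        ]

    def test_all_resistant_signs_binomial_closed_form(self):
        samples = _annotations(6, ["lung"], mets=3)
        summaries = self._summaries(
            samples, lambda ann, j, rng: 0.7 + (0.1 if ann.is_metastasis else 0.0)
        )
        res = met_vs_primary_auc(summaries, samples)
        assert res["n_pairs"] == 10 and res["n_met_resistant"] == 10
        assert res["binomial_p"] == pytest.approx(2.0 ** -10)

    def test_five_of_ten_binomial(self):
        assert stats.binomtest(5, 10, 0.5, alternative="greater").pvalue == pytest.approx(
            0.623, abs=0.001
        )

    def test_disease_without_both_strata_excluded(self):
        samples = _annotations(4, ["lung", "liver"], mets=0)
        samples["m0"] = SampleAnnotation(
            sample_id="m0", study_id="st", oncotree_code="D_lung",
            primary_site="lung", is_metastasis=True, metastatic_site="liver",
        )
        summaries = self._summaries(samples, lambda a, j, rng: rng.normal(0.6, 0.01))
        res = met_vs_primary_auc(summaries, samples)
        assert set(res["table"]["disease"]) == {"D_lung"}

    def test_soc_restricted_rank_comparison_runs(self):
        samples = _annotations(8, ["lung"], mets=4)
        rng = np.random.default_rng(2)
        summaries = self._summaries(
            samples,
            lambda ann, j, rng: rng.normal(0.6, 0.02) + (0.08 if ann.is_metastasis else 0),
            rng=rng,
        )
        res = met_vs_primary_auc(summaries, samples, {"D_lung": {"d0", "d1", "d2"}})
        assert res["soc_rank_diff"] > 0 and res["soc_mannwhitney_p"] < 0.05

    def test_met_sensitive_class_positive_ci(self):
        samples = _annotations(12, ["lung", "liver"], mets=5)
        rng = np.random.default_rng(3)
        rows = []
        for sid, ann in samples.items():
            for j in range(12):
                shift = 1.5 if (ann.is_metastasis and j < 6) else 0.0
                rows.append({"sample_id": sid, "drug_id": f"d{j}", "z": rng.normal() + shift})
        z = pd.DataFrame(rows)
        group = {f"d{j}": ("classA" if j < 6 else "classB") for j in range(12)}
        res = met_vs_primary_zdiff(z, samples, group, min_met=3, n_boot=300, seed=0)
        hit = res["hits"][(res["hits"]["unit"] == "classA")]
        assert (hit["effect"] > 0).all() and (hit["ci_lo"] > 0).all()

    def test_identical_difference_vectors_cluster_adjacent(self):
        samples = _annotations(12, ["lung", "liver", "skin"], mets=5)
        rng = np.random.default_rng(4)
        rows = []
        # classA and classB get identical disease-profiles, classC differs
        prof = {"D_lung": 1.0, "D_liver": -1.0, "D_skin": 0.5}
        for sid, ann in samples.items():
            for j in range(15):
                cls = ["A", "A", "B", "B", "C"][j % 5]
                shift = 0.0
                if ann.is_metastasis:
                    shift = prof[ann.oncotree_code] * (1 if cls in "AB" else -1)
                rows.append({"sample_id": sid, "drug_id": f"d{j}",
                             "z": rng.normal(0, 0.05) + shift})
        z = pd.DataFrame(rows)
        group = {f"d{j}": "class" + ["A", "A", "B", "B", "C"][j % 5] for j in range(15)}
        res = met_vs_primary_zdiff(z, samples, group, min_met=3, n_boot=50, seed=0)
        order = res["leaf_order"]
        assert abs(order.index("classA") - order.index("classB")) == 1


class TestCellLineVsExVivo:
    def _mixed_cohort(self, shift_by_class, rng, n=8, n_drugs=12,
                      tissues=("lung", "liver")):
        samples = {}
        rows = []
        for mod in ("cell_line", "PDC"):
            for t in tissues:
                for k in range(n):
                    sid = f"{mod}_{t}_{k}"
                    samples[sid] = SampleAnnotation(
                        sample_id=sid, study_id="st", oncotree_code=f"D_{t}",
                        primary_site=t, model_type=mod,
                    )
                    for j in range(n_drugs):
                        cls = "cycling" if j < n_drugs // 2 else "signaling"
                        shift = shift_by_class.get(cls, 0.0) if mod == "cell_line" else 0.0
                        rows.append({"sample_id": sid, "drug_id": f"d{j}",
                                     "z": rng.normal() + shift})
        cls_map = {f"d{j}": ("cycling" if j < n_drugs // 2 else "signaling")
                   for j in range(n_drugs)}
        return samples, pd.DataFrame(rows), cls_map

    def test_planted_cellline_shift_detected_consistently(self):
        rng = np.random.default_rng(0)
        samples, z, cls = self._mixed_cohort({"cycling": 1.5}, rng)
        res = cellline_vs_exvivo(z, samples, cls, B=299, seed=0)
        hits = res["hits"]
        cyc = hits[hits["unit"] == "cycling"]
        assert (cyc["effect"] > 0).all() and (cyc["q"] < 0.1).all()
        per_class = res["per_class"].set_index("unit")
        assert per_class.loc["cycling", "fisher_p"] < per_class.loc["signaling", "fisher_p"]

    def test_null_false_positive_rate_controlled(self):
        n_sig, n_tests = 0, 0
        for seed in range(4):
            rng = np.random.default_rng(seed + 10)
            samples, z, cls = self._mixed_cohort({}, rng)
            res = cellline_vs_exvivo(z, samples, cls, B=199, seed=seed)
            n_sig += (res["hits"]["q"] < 0.1).sum()
            n_tests += len(res["hits"])
        assert n_sig <= 0.1 * n_tests + 2

    def test_paired_ranking_comparison(self):
        rng = np.random.default_rng(1)
        samples, z, cls = self._mixed_cohort(
            {"cycling": 1.2, "signaling": -1.2}, rng,
            tissues=("lung", "liver", "skin", "bone"),
        )
        groups = paired_group_ranking(
            z, samples,
            {d for d, c in cls.items() if c == "cycling"},
            {d for d, c in cls.items() if c == "signaling"},
        )
        assert groups["cell_cycling"]["mean_diff"] > 0
        assert groups["cell_signaling"]["mean_diff"] < 0
        assert groups["cell_cycling"]["t_p"] < 0.05

    def test_favoring_share(self):
        assert favoring_share(234, 700) == pytest.approx(33.43, abs=0.01)
        with pytest.raises(ValidationError):
            favoring_share(1, 0)


class TestKNN:
    def test_separated_clusters_full_purity(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.1, (10, 3)), rng.normal(10, 0.1, (10, 3))])
        labels = ["a"] * 10 + ["b"] * 10
        res = knn_label_analysis(x, labels, k=5, mode="disease_purity")
        assert res["overall_purity"] == 1.0
        assert (res["per_label"]["purity"] == 1.0).all()

    def test_shuffled_labels_purity_near_prevalence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(120, 4))
        labels = rng.permutation(["a"] * 60 + ["b"] * 60)
        res = knn_label_analysis(x, labels, k=5, mode="disease_purity")
        assert abs(res["overall_purity"] - 0.5) < 0.15

    def test_modality_fisher_comparison(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.1, (12, 3)), rng.normal(5, 3.0, (12, 3))])
        labels = ["a"] * 6 + ["b"] * 6 + ["a"] * 6 + ["b"] * 6
        modality = ["ev"] * 12 + ["cl"] * 12
        res = knn_label_analysis(x, labels, k=3, mode="disease_purity", modality=modality)
        assert "modality_fisher_p" in res

    def test_mutation_enrichment_detects_clustered_mutants(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.2, (15, 2)), rng.normal(8, 0.2, (15, 2))])
        mut = pd.DataFrame({"G": [1] * 15 + [0] * 15})
        res = knn_label_analysis(x, [""] * 30, k=1, mode="mutation_enrichment",
                                 mutations=mut)
        row = res["per_gene"].iloc[0]
        assert row["frac_mut"] == 1.0 and row["frac_wt"] == 0.0 and row["q"] < 0.01

    def test_tmb_latent_correlation_near_one(self):
        rng = np.random.default_rng(4)
        latent = rng.normal(size=40)
        x = np.column_stack([latent, latent])  # embedding = latent, 1-NN shares it
        tmb = 20 + 10 * latent
        res = knn_label_analysis(x, [""] * 40, k=1, mode="tmb_correlation", tmb=tmb,
                                 n_boot=200)
        assert res["r"] > 0.95 and res["ci"][0] > 0.8

    def test_k_geq_n_errors(self):
        with pytest.raises(ConfigError):
            knn_label_analysis(np.zeros((3, 2)), ["a"] * 3, k=3, mode="disease_purity")
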