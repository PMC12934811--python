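"""Population-level comparisons of de-batched z-scores and AUC summaries.

Covers the pipeline's statistical readouts: per-(tissue, drug) differential
sensitivity against all other tissues, metastatic-vs-primary comparisons on
both raw AUCs (sign / binomial and rank tests) and z-score differences with
bootstrap intervals and hierarchical clustering, cell-line-vs-ex-vivo class
deviations with permutation tests and Fisher-combined per-class p-values, and
k-nearest-neighbor analyses of embedding spaces (disease purity, mutation
enrichment, TMB correlation).

Conventions: Welch t-tests wherever a t-test is unqualified; minimum group
size 3; Benjamini–Hochberg FDR with a default threshold of 0.1.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .metrics import CurveSummary
from .screen_data import SampleAnnotation

HIT_COLUMNS = ["unit", "stratum", "effect", "n_a", "n_b", "p", "q", "direction"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_test(
    values_a, values_b, B: int = 999, seed: int = 0, min_n: int = 3
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of means.

    Returns (p, observed statistic) with the add-one floor
    p = (1 + #{|stat_perm| >= |stat_obs|}) / (B + 1)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if B < 1:
        raise ConfigError("B must be >= 1")
    if len(a) < min_n or len(b) < min_n:
        raise ValidationError(f"both groups need >= {min_n} values")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(pooled)
        stat = perm[: len(a)].mean() - perm[len(a):].mean()
        if abs(stat) >= abs(obs):
            count += 1
    return (1 + count) / (B + 1), float(obs)


def fisher_method(p_values) -> tuple[float, float]:
    """Fisher's combination: chi2 = -2 sum(ln p) on 2k d.o.f. Returns (p, chi2)."""
    p = np.asarray(list(p_values), float)
    chi2 = -2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0)))
    return float(stats.chi2.sf(chi2, df=2 * len(p))), float(chi2)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def tissue_vs_rest(
    z: pd.DataFrame,
    samples: Mapping[str, SampleAnnotation],
    min_n: int = 3,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-(tissue, drug) differential sensitivity vs all other tissues.

    Restricted to primary samples; tissues with fewer than `min_n` samples are
    excluded. Effect = mean z in tissue minus mean z elsewhere; Welch t-test,
    BH across all (tissue, drug) pairs; `hit` flags q < fdr."""
    z = z.dropna(subset=["z"]).copy()
    z["tissue"] = z["sample_id"].map(
        lambda s: samples[s].primary_site if not samples[s].is_metastasis else None
    )
    z = z.dropna(subset=["tissue"])
    tissue_sizes = z.groupby("tissue")["sample_id"].nunique()
    eligible = set(tissue_sizes.index[tissue_sizes >= min_n])
    z = z[z["tissue"].isin(eligible)]
    if z.empty or len(eligible) < 2:
        import warnings

        warnings.warn("no eligible tissues for differential analysis")
        return pd.DataFrame(columns=HIT_COLUMNS + ["hit"])
    rows = []
    for drug_id, sub in z.groupby("drug_id"):
        for tissue in sorted(eligible):
            a = sub.loc[sub["tissue"] == tissue, "z"].to_numpy()
            b = sub.loc[sub["tissue"] != tissue, "z"].to_numpy()
            if len(a) < min_n or len(b) < min_n:
                continue
            rows.append(
                {
                    "unit": drug_id, "stratum": tissue,
                    "effect": a.mean() - b.mean(),
                    "n_a": len(a), "n_b": len(b), "p": _welch(a, b),
                }
            )
    hits = pd.DataFrame(rows)
    if hits.empty:
        return pd.DataFrame(columns=HIT_COLUMNS + ["hit"])
    hits["q"] = bh_adjust(hits["p"])
    hits["direction"] = np.where(hits["effect"] > 0, "sensitive", "resistant")
    hits["hit"] = hits["q"] < fdr
    return hits[HIT_COLUMNS + ["hit"]]


def met_vs_primary_auc(
    summaries: Sequence[CurveSummary],
    samples: Mapping[str, SampleAnnotation],
    soc_of_disease: Mapping[str, set] | None = None,
) -> dict:
    """Absolute-resistance comparison on AUCs.

    Per (disease, drug) pair with both strata present, computes the sign of
    mean AUC(met) - mean AUC(primary) (positive = metastasis more resistant),
    and a one-sided binomial test that resistant signs exceed 1/2. When
    standard-of-care annotations are given, also runs a two-sided Mann-Whitney
    U on within-(disease, drug) AUC ranks of met vs primary samples restricted
    to each disease's standard-of-care drugs."""
    df = pd.DataFrame(
        [
            {
                "disease": samples[s.sample_id].oncotree_code,
                "is_met": samples[s.sample_id].is_metastasis,
                "drug_id": s.drug_id, "auc": s.auc, "sample_id": s.sample_id,
            }
            for s in summaries
        ]
    )
    per_pair = []
    for (disease, drug), sub in df.groupby(["disease", "drug_id"]):
        met = sub.loc[sub["is_met"], "auc"]
        pri = sub.loc[~sub["is_met"], "auc"]
        if len(met) == 0 or len(pri) == 0:
            continue
        per_pair.append(
            {"disease": disease, "drug_id": drug,
             "diff": met.mean() - pri.mean()}
        )
    table = pd.DataFrame(per_pair)
    if table.empty:
        raise ValidationError("no disease has both primary and metastatic samples")
    n_resistant = int((table["diff"] > 0).sum())
    n_total = int((table["diff"] != 0).sum())
    binom_p = float(stats.binomtest(n_resistant, n_total, 0.5, alternative="greater").pvalue)

    out = {"table": table, "n_met_resistant": n_resistant, "n_pairs": n_total,
           "binomial_p": binom_p}
    if soc_of_disease is not None:
        ranks_met, ranks_pri = [], []
        for (disease, drug), sub in df.groupby(["disease", "drug_id"]):
            if drug not in soc_of_disease.get(disease, set()):
                continue
            if sub["is_met"].nunique() < 2 or len(sub) < 2:
                continue
            r = stats.rankdata(sub["auc"]) / len(sub)
            ranks_met.extend(r[sub["is_met"].to_numpy()])
            ranks_pri.extend(r[~sub["is_met"].to_numpy()])
        if ranks_met and ranks_pri:
            mw = stats.mannwhitneyu(ranks_met, ranks_pri, alternative="two-sided")
            out["soc_mannwhitney_p"] = float(mw.pvalue)
            out["soc_rank_diff"] = float(np.mean(ranks_met) - np.mean(ranks_pri))
    return out


def met_vs_primary_zdiff(
    z: pd.DataFrame,
    samples: Mapping[str, SampleAnnotation],
    group_of_drug: Mapping[str, str],
    min_met: int = 3,
    n_boot: int = 1000,
    ci: float = 0.90,
    seed: int = 0,
) -> dict:
    """Relative met-vs-primary sensitivity by drug group, per disease.

    Per (disease, group): effect = mean z(met) - mean z(primary); Mann-Whitney
    U + BH per group across diseases; percentile bootstrap CIs over samples;
    average-linkage clustering on the Pearson-correlation distance between
    disease-wise difference vectors, with a leaf ordering."""
    rng = np.random.default_rng(seed)
    z = z.dropna(subset=["z"]).copy()
    z["group"] = z["drug_id"].map(group_of_drug)
    z = z.dropna(subset=["group"])
    z["disease"] = z["sample_id"].map(lambda s: samples[s].oncotree_code)
    z["is_met"] = z["sample_id"].map(lambda s: samples[s].is_metastasis)

    met_counts = z[z["is_met"]].groupby("disease")["sample_id"].nunique()
    diseases = sorted(met_counts.index[met_counts >= min_met])
    z = z[z["disease"].isin(diseases)]
    rows = []
    for (disease, group), sub in z.groupby(["disease", "group"]):
        met = sub.loc[sub["is_met"]]
        pri = sub.loc[~sub["is_met"]]
        if met["sample_id"].nunique() < min_met or len(pri) == 0:
            continue
        effect = met["z"].mean() - pri["z"].mean()
        p = float(stats.mannwhitneyu(met["z"], pri["z"], alternative="two-sided").pvalue)
        # percentile bootstrap over samples within each stratum
        met_by = [g["z"].to_numpy() for _, g in met.groupby("sample_id")]
        pri_by = [g["z"].to_numpy() for _, g in pri.groupby("sample_id")]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            mb = [met_by[i] for i in rng.integers(0, len(met_by), len(met_by))]
            pb = [pri_by[i] for i in rng.integers(0, len(pri_by), len(pri_by))]
            boots[b] = np.concatenate(mb).mean() - np.concatenate(pb).mean()
        alpha = (1.0 - ci) / 2
        rows.append(
            {"unit": group, "stratum": disease, "effect": effect,
             "n_a": met["sample_id"].nunique(), "n_b": pri["sample_id"].nunique(),
             "p": p, "ci_lo": float(np.quantile(boots, alpha)),
             "ci_hi": float(np.quantile(boots, 1 - alpha))}
        )
    hits = pd.DataFrame(rows)
    if not hits.empty:
        hits["q"] = bh_adjust(hits["p"])
        hits["direction"] = np.where(hits["effect"] > 0, "met_sensitive", "met_resistant")

    # clustering of group-wise disease-difference vectors
    order = list(hits["unit"].unique()) if not hits.empty else []
    linkage = None
    if not hits.empty and hits["unit"].nunique() >= 3:
        mat = hits.pivot_table(index="unit", columns="stratum", values="effect")
        mat = mat.dropna(axis=0, thresh=2)
        if len(mat) >= 3:
            corr = np.corrcoef(mat.fillna(mat.mean(axis=None)).to_numpy())
            dist = np.clip(1.0 - corr, 0.0, 2.0)
            np.fill_diagonal(dist, 0.0)
            linkage = average(squareform(dist, checks=False))
            order = [mat.index[i] for i in leaves_list(linkage)]
    return {"hits": hits, "leaf_order": order, "linkage": linkage}


def cellline_vs_exvivo(
    z: pd.DataFrame,
    samples: Mapping[str, SampleAnnotation],
    class_of_drug: Mapping[str, str],
    min_n: int = 3,
    B: int = 499,
    seed: int = 0,
) -> dict:
    """Cell-line minus ex-vivo mean z per (disease, status, drug class).

    Permutation test per stratum, BH across strata, and per-class aggregate
    p across diseases via Fisher's method."""
    z = z.dropna(subset=["z"]).copy()
    z["cls"] = z["drug_id"].map(class_of_drug)
    z = z.dropna(subset=["cls"])
    z["disease"] = z["sample_id"].map(lambda s: samples[s].oncotree_code)
    z["status"] = z["sample_id"].map(
        lambda s: "metastasis" if samples[s].is_metastasis else "primary"
    )
    z["modality"] = z["sample_id"].map(
        lambda s: "cell_line" if samples[s].model_type == "cell_line" else "ex_vivo"
    )
    rows = []
    rng = np.random.default_rng(seed)
    for (disease, status, cls), sub in z.groupby(["disease", "status", "cls"]):
        cl = sub.loc[sub["modality"] == "cell_line", "z"].to_numpy()
        ev = sub.loc[sub["modality"] == "ex_vivo", "z"].to_numpy()
        if len(cl) < min_n or len(ev) < min_n:
            continue
        p, effect = permutation_test(cl, ev, B=B, seed=int(rng.integers(2**31)), min_n=min_n)
        rows.append(
            {"unit": cls, "stratum": f"{disease}|{status}", "disease": disease,
             "status": status, "effect": effect, "n_a": len(cl), "n_b": len(ev), "p": p}
        )
    hits = pd.DataFrame(rows)
    per_class = pd.DataFrame()
    if not hits.empty:
        hits["q"] = bh_adjust(hits["p"])
        hits["direction"] = np.where(hits["effect"] > 0, "cellline_sensitive",
                                     "exvivo_sensitive")
        agg = []
        for cls, sub in hits.groupby("unit"):
            p_comb, chi2 = fisher_method(sub["p"])
            agg.append(
                {"unit": cls, "n_strata": len(sub), "mean_effect": sub["effect"].mean(),
                 "fisher_p": p_comb, "chi2": chi2}
            )
        per_class = pd.DataFrame(agg)
        per_class["q"] = bh_adjust(per_class["fisher_p"])
    return {"hits": hits, "per_class": per_class}


def favoring_share(n_favoring: int, n_total: int) -> float:
    """Percentage of significant modality differences favoring one side."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    return 100.0 * n_favoring / n_total


def paired_group_ranking(
    z: pd.DataFrame,
    samples: Mapping[str, SampleAnnotation],
    group_a_drugs: set,
    group_b_drugs: set,
    label_a: str = "cell_cycling",
    label_b: str = "cell_signaling",
) -> dict:
    """Paired per-disease comparison of normalized drug rankings by modality.

    Normalized ranking = per-sample rank of each drug's z divided by the
    sample's panel size (higher = comparatively more efficacious), averaged
    within each drug group, then within (disease, modality). A two-tailed
    paired t-test compares cell-line vs ex-vivo means across diseases for each
    group."""
    z = z.dropna(subset=["z"]).copy()
    z["rank"] = z.groupby("sample_id")["z"].rank(pct=True)
    z["disease"] = z["sample_id"].map(lambda s: samples[s].oncotree_code)
    z["modality"] = z["sample_id"].map(
        lambda s: "cell_line" if samples[s].model_type == "cell_line" else "ex_vivo"
    )
    out_rows = []
    for label, drugs in ((label_a, group_a_drugs), (label_b, group_b_drugs)):
        sub = z[z["drug_id"].isin(drugs)]
        cell = sub.groupby(["disease", "modality"])["rank"].mean().unstack()
        if cell is None or "cell_line" not in cell or "ex_vivo" not in cell:
            continue
        paired = cell.dropna()
        res = {"group": label, "per_disease": paired}
        if len(paired) >= 2:
            t = stats.ttest_rel(paired["cell_line"], paired["ex_vivo"])
            res["t_p"] = float(t.pvalue)
            res["mean_diff"] = float((paired["cell_line"] - paired["ex_vivo"]).mean())
        out_rows.append(res)
    return {r["group"]: r for r in out_rows}


def knn_label_analysis(
    embeddings: np.ndarray,
    labels: Sequence,
    k: int = 5,
    mode: str = "disease_purity",
    modality: Sequence | None = None,
    mutations: pd.DataFrame | None = None,
    tmb: Sequence | None = None,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Nearest-neighbor structure of an embedding space (Euclidean metric).

    Modes
    -----
    disease_purity: per sample, does the majority label among the k neighbors
        match its own label; per-label fraction with a two-sided binomial test
        against the label's prevalence (BH), plus a global two-sided Fisher
        exact test comparing modality groups when `modality` is given.
    mutation_enrichment: per gene (columns of `mutations`, indexed like
        `embeddings` rows), fraction of samples whose 1-NN is mutated,
        stratified by own status; two-sided Fisher exact + BH.
    tmb_correlation: Pearson r between own TMB and 1-NN TMB with a percentile
        bootstrap CI.
    """
    x = np.asarray(embeddings, float)
    n = len(x)
    if k >= n:
        raise ConfigError(f"k={k} must be < n={n}")
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_order = np.argsort(d2, axis=1)

    if mode == "disease_purity":
        labels = np.asarray(labels, dtype=object)
        correct = np.empty(n, bool)
        for i in range(n):
            neigh = labels[nn_order[i, :k]]
            vals, counts = np.unique(neigh.astype(str), return_counts=True)
            correct[i] = vals[np.argmax(counts)] == str(labels[i])
        per_label = []
        for lab in sorted(set(map(str, labels))):
            mask = labels.astype(str) == lab
            prev = mask.mean()
            n_corr = int(correct[mask].sum())
            p = float(stats.binomtest(n_corr, int(mask.sum()), prev).pvalue)
            per_label.append(
                {"label": lab, "n": int(mask.sum()), "purity": n_corr / mask.sum(),
                 "prevalence": prev, "p": p}
            )
        table = pd.DataFrame(per_label)
        table["q"] = bh_adjust(table["p"])
        out = {"per_label": table, "overall_purity": float(correct.mean())}
        if modality is not None:
            modality = np.asarray(modality, dtype=object)
            groups = sorted(set(map(str, modality)))
            if len(groups) == 2:
                a = modality.astype(str) == groups[0]
                contingency = [
                    [int(correct[a].sum()), int((~correct[a]).sum())],
                    [int(correct[~a].sum()), int((~correct[~a]).sum())],
                ]
                out["modality_fisher_p"] = float(stats.fisher_exact(contingency)[1])
                out["modality_purity"] = {
                    groups[0]: float(correct[a].mean()),
                    groups[1]: float(correct[~a].mean()),
                }
        return out

    if mode == "mutation_enrichment":
        if mutations is None:
            raise ConfigError("mutation_enrichment needs a mutations frame")
        nn1 = nn_order[:, 0]
        rows = []
        for gene in mutations.columns:
            own = mutations[gene].to_numpy() > 0
            if own.all() or (~own).all():
                rows.append({"gene": gene, "skipped": True, "p": np.nan,
                             "frac_mut": np.nan, "frac_wt": np.nan})
                continue
            neigh_mut = mutations[gene].to_numpy()[nn1] > 0
            contingency = [
                [int(neigh_mut[own].sum()), int((~neigh_mut[own]).sum())],
                [int(neigh_mut[~own].sum()), int((~neigh_mut[~own]).sum())],
            ]
            rows.append(
                {"gene": gene, "skipped": False,
                 "frac_mut": float(neigh_mut[own].mean()),
                 "frac_wt": float(neigh_mut[~own].mean()),
                 "p": float(stats.fisher_exact(contingency)[1])}
            )
        table = pd.DataFrame(rows)
        ok = ~table["skipped"]
        q = np.full(len(table), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_adjust(table.loc[ok, "p"])
        table["q"] = q
        return {"per_gene": table}

    if mode == "tmb_correlation":
        if tmb is None:
            raise ConfigError("tmb_correlation needs tmb values")
        tmb = np.asarray(tmb, float)
        nn1 = nn_order[:, 0]
        r, p = stats.pearsonr(tmb, tmb[nn1])
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.std(tmb[idx]) == 0 or np.std(tmb[nn1][idx]) == 0:
                continue
            boots.append(stats.pearsonr(tmb[idx], tmb[nn1][idx])[0])
        alpha = (1 - ci) / 2
        return {
            "r": float(r), "p": float(p),
            "ci": (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha))),
        }

    raise ConfigError(f"unknown mode {mode!r}")
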