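"""Evaluation harnesses: curve-holdout CV, study-ablation matrix, power
analysis for pilot-screen designs, classical baselines, and the few-shot
benchmark for the transformer.

All cross-validation holds out *whole dose-response curves* (every record of a
(study, sample, drug) triple lands in exactly one test fold), so evaluation
never leaks partial curves into training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import ConfigError, ValidationError
from .screen_data import ScreenDataset


@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 5
    seed: int = 0


def curve_folds(ds: ScreenDataset, plan: CVPlan) -> list[set]:
    """Partition curves (study, sample, drug) into folds; exact partition."""
    keys = sorted(
        set(map(tuple, ds.records[["study_id", "sample_id", "drug_id"]].to_numpy()))
    )
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(keys))
    folds = [set() for _ in range(plan.n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % plan.n_folds].add(keys[idx])
    return folds


def _split_by_curves(ds: ScreenDataset, test_keys: set):
    key = list(map(tuple, ds.records[["study_id", "sample_id", "drug_id"]].to_numpy()))
    mask = np.array([k in test_keys for k in key])
    train = ScreenDataset(ds.records[~mask], samples=ds.samples, drugs=ds.drugs)
    test = ds.records[mask].copy()
    return train, test


def _stratified_metrics(df: pd.DataFrame, by: str, min_n: int = 3) -> pd.DataFrame:
    rows = []
    for stratum, sub in df.groupby(by):
        n = len(sub)
        if n < min_n or sub["y"].std() == 0 or sub["pred"].std() == 0:
            rows.append({by: stratum, "n": n, "pearson_r": np.nan, "spearman_r": np.nan,
                         "rmse": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(sub["y"], sub["pred"])
        rho = stats.spearmanr(sub["y"], sub["pred"]).statistic
        rows.append({by: stratum, "n": n, "pearson_r": float(r),
                     "spearman_r": float(rho),
                     "rmse": float(np.sqrt(np.mean((sub["y"] - sub["pred"]) ** 2))),
                     "p": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"])
    out["q"] = q
    out["significant"] = out["q"] < 0.05
    return out


def cv_curve_holdout(
    ds: ScreenDataset,
    model_factory: Callable[[ScreenDataset], object],
    plan: CVPlan = CVPlan(),
    min_n: int = 3,
) -> dict:
    """Five-fold whole-curve-holdout CV with stratified correlation reports.

    `model_factory(train_ds)` must return an object with
    ``predict(sample_id, drug_id, log10_concs) -> viabilities``.
    Returns per-stratum tables (disease, mechanism, sample, concentration bin)
    plus the pooled prediction frame."""
    folds = curve_folds(ds, plan)
    all_keys = set().union(*folds)
    assert sum(len(f) for f in folds) == len(all_keys), "folds must partition curves"
    preds = []
    for fold in folds:
        train, test = _split_by_curves(ds, fold)
        model = model_factory(train)
        for (study, sid, did), grp in test.groupby(["study_id", "sample_id", "drug_id"]):
            logc = np.log10(grp["concentration_uM"].to_numpy(float))
            try:
                yhat = model.predict(sid, did, logc)
            except KeyError:
                continue  # entity absent from training fold
            for c, y, p in zip(logc, grp["viability"], yhat):
                preds.append(
                    {"study_id": study, "sample_id": sid, "drug_id": did,
                     "log10_conc": c, "y": y, "pred": p}
                )
    df = pd.DataFrame(preds)
    df["disease"] = df["sample_id"].map(lambda s: ds.samples[s].oncotree_code)
    df["mechanism"] = df["drug_id"].map(lambda d: ds.drugs[d].first_mechanism)
    df["conc_bin"] = df["log10_conc"].round(0)
    return {
        "predictions": df,
        "by_disease": _stratified_metrics(df, "disease", min_n),
        "by_mechanism": _stratified_metrics(df, "mechanism", min_n),
        "by_sample": _stratified_metrics(df, "sample_id", min_n),
        "by_concentration": _stratified_metrics(df, "conc_bin", min_n),
    }


def drm_predictor(model, S: int = 8):
    """Adapt a FittedDoseModel to the predict(sample, drug, logc) interface."""

    class _P:
        def predict(self, sample_id, drug_id, logc):
            draws, _ = model.posterior_curve_draws(
                sample_id, drug_id, query_logconcs=logc, S=S
            )
            return draws.mean(axis=0)

    return _P()


def drm_factory(cfg, S: int = 8):
    """Model factory fitting the dose-response model with a fixed config."""
    from .dose_model import fit

    def factory(train_ds: ScreenDataset):
        return drm_predictor(fit(train_ds, cfg), S=S)

    return factory


def ablation_matrix(
    ds: ScreenDataset,
    model_factory: Callable[[ScreenDataset], object],
    n_drug_folds: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Donor×target improvement matrix under whole-drug holdout.

    For each target study, each of its drugs' curve sets is held out in turn
    (grouped into `n_drug_folds` batches); the remaining data — with or
    without each donor study — trains the model. Cells report the fraction of
    held-out curves whose RMSE improves when the donor is present, with a
    one-sided binomial test and BH correction; the diagonal is excluded."""
    studies = ds.study_ids
    if len(studies) < 2:
        raise ValidationError("ablation requires >= 2 studies")
    rng = np.random.default_rng(seed)

    def heldout_errors(train: ScreenDataset, test: pd.DataFrame) -> dict:
        model = model_factory(train)
        errs = {}
        for (study, sid, did), grp in test.groupby(["study_id", "sample_id", "drug_id"]):
            logc = np.log10(grp["concentration_uM"].to_numpy(float))
            try:
                yhat = model.predict(sid, did, logc)
            except KeyError:
                continue
            errs[(study, sid, did)] = float(
                np.sqrt(np.mean((grp["viability"].to_numpy() - yhat) ** 2))
            )
        return errs

    rows = []
    for target in studies:
        target_drugs = sorted(set(ds.records.loc[ds.records["study_id"] == target, "drug_id"]))
        order = rng.permutation(len(target_drugs))
        batches = [
            [target_drugs[i] for i in order[b::n_drug_folds]] for b in range(n_drug_folds)
        ]
        with_errs: dict = {}
        without_errs: dict[str, dict] = {d: {} for d in studies if d != target}
        for batch in batches:
            test_mask = (ds.records["study_id"] == target) & ds.records["drug_id"].isin(batch)
            test = ds.records[test_mask].copy()
            full_train = ScreenDataset(ds.records[~test_mask], samples=ds.samples, drugs=ds.drugs)
            with_errs.update(heldout_errors(full_train, test))
            for donor in without_errs:
                sub = full_train.records[full_train.records["study_id"] != donor]
                train = ScreenDataset(sub, samples=ds.samples, drugs=ds.drugs)
                without_errs[donor].update(heldout_errors(train, test))
        for donor in without_errs:
            common = sorted(set(with_errs) & set(without_errs[donor]))
            if not common:
                continue
            improved = sum(with_errs[k] < without_errs[donor][k] for k in common)
            p = stats.binomtest(improved, len(common), 0.5, alternative="greater").pvalue
            rows.append(
                {"donor": donor, "target": target, "n_curves": len(common),
                 "frac_improved": improved / len(common), "p": float(p)}
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
        out["significant"] = out["q"] < 0.1
    return out


def model_ranker(model, seed: int = 0):
    """Rank candidate drugs by model-predicted IC50 after pilot embedding.

    Ties broken by lower predicted AUC then lexicographic drug id."""
    from .dose_model import embed_new_sample
    from .metrics import auc, ic50

    def rank(pilot_records, candidate_drugs):
        v_mean, v_sd = embed_new_sample(model, pilot_records, seed=seed)
        scored = []
        for did in candidate_drugs:
            draws, grid = model.posterior_curve_draws(
                None, did, S=8, v_override=(v_mean, v_sd),
                rng=np.random.default_rng(seed),
            )
            curve = np.minimum.accumulate(draws.mean(axis=0))
            val, cens = ic50(curve, grid)
            penalty = {"above_max": 1.0, "below_min": 0.0, None: 0.0}[cens]
            scored.append((val + 10 * penalty, auc(curve, grid), did))
        return [d for _, _, d in sorted(scored)]

    return rank


def power_analysis(
    sample_screens: Mapping[str, Sequence[tuple]],
    true_best: Mapping[str, str],
    ranker: Callable,
    pilot_sizes: Sequence[int] = (10, 20, 50),
    budgets: Sequence[int] = tuple(range(1, 51)),
    n_seeds: int = 3,
    seed: int = 0,
    include_pilot_hits: bool = True,
) -> pd.DataFrame:
    """Power to find the panel's true top hit under a pilot + budget design.

    `sample_screens[sid]` is the sample's full panel of
    (drug_id, concentration_uM, viability) records; `true_best[sid]` names the
    lowest-IC50 drug in its panel. A random pilot of `pilot` drugs is screened,
    the ranker orders the remaining drugs, and success means the top hit lies
    in pilot ∪ top-budget predictions (pilot hits excluded when
    `include_pilot_hits` is False). Power is the success fraction across
    samples × seeds; monotone non-decreasing in budget by construction."""
    if min(budgets) < 1 and not include_pilot_hits:
        raise ConfigError("budget must be >= 1")
    if min(budgets) < 0:
        raise ConfigError("budget must be >= 0 (0 allowed only with pilot hits)")
    rows = []
    for pilot_n in pilot_sizes:
        successes = {b: 0 for b in budgets}
        trials = 0
        for rep in range(n_seeds):
            rng = np.random.default_rng(seed + rep)
            for sid, records in sample_screens.items():
                drugs = sorted({r[0] for r in records})
                if len(drugs) <= pilot_n:
                    continue
                pilot_drugs = set(
                    rng.choice(drugs, size=pilot_n, replace=False).tolist()
                )
                pilot_records = [r for r in records if r[0] in pilot_drugs]
                candidates = [d for d in drugs if d not in pilot_drugs]
                ranked = ranker(pilot_records, candidates)
                best = true_best[sid]
                trials += 1
                in_pilot = best in pilot_drugs and include_pilot_hits
                for b in budgets:
                    if in_pilot or best in ranked[:b]:
                        successes[b] += 1
        for b in budgets:
            rows.append(
                {"pilot": pilot_n, "budget": b,
                 "power": successes[b] / trials if trials else np.nan,
                 "n_trials": trials}
            )
    return pd.DataFrame(rows)


# -- baselines --------------------------------------------------------------

BASELINE_KINDS = ("bucket_mean", "tree_ensemble", "feedforward_net", "ridge",
                  "boosted_trees", "context_mean")


def _feature_frame(rec: pd.DataFrame, drug_levels, study_levels):
    drug = pd.Categorical(rec["drug_id"], categories=drug_levels)
    study = pd.Categorical(rec["study_id"], categories=study_levels)
    x = np.column_stack(
        [
            pd.get_dummies(drug, dtype=float).to_numpy(),
            pd.get_dummies(study, dtype=float).to_numpy(),
            np.log10(rec["concentration_uM"].to_numpy(float))[:, None],
        ]
    )
    return x


def baseline_predict(
    kind: str, train: pd.DataFrame, test: pd.DataFrame,
    seed: int = 0, ridge_alpha: float = 1.0,
) -> np.ndarray:
    """Classical predictors on one-hot drug/study + log10 dose features.

    `train`/`test` are record frames in the screen_data column layout.
    bucket_mean averages per (drug, dose) bucket with drug-mean then
    global-mean fallback; context_mean predicts each sample's training-set
    mean viability."""
    if kind not in BASELINE_KINDS:
        raise ConfigError(f"unknown baseline kind {kind!r}")
    y = train["viability"].to_numpy(float)
    if kind == "bucket_mean":
        tmp = pd.DataFrame(
            {"d": train["drug_id"].to_numpy(),
             "c": np.round(np.log10(train["concentration_uM"].to_numpy(float)), 6),
             "y": y}
        )
        bucket = tmp.groupby(["d", "c"])["y"].mean()
        drug_mean = train.groupby("drug_id")["viability"].mean()
        global_mean = y.mean()
        out = []
        for d, c in zip(test["drug_id"], np.round(np.log10(test["concentration_uM"].to_numpy(float)), 6)):
            if (d, c) in bucket.index:
                out.append(bucket.loc[(d, c)])
            elif d in drug_mean.index:
                out.append(drug_mean[d])
            else:
                out.append(global_mean)
        return np.array(out)
    if kind == "context_mean":
        sm = train.groupby("sample_id")["viability"].mean()
        gm = y.mean()
        return test["sample_id"].map(sm).fillna(gm).to_numpy(float)

    drug_levels = sorted(set(train["drug_id"]) | set(test["drug_id"]))
    study_levels = sorted(set(train["study_id"]) | set(test["study_id"]))
    xtr = _feature_frame(train, drug_levels, study_levels)
    xte = _feature_frame(test, drug_levels, study_levels)
    if kind == "ridge":
        from sklearn.linear_model import LinearRegression, Ridge

        reg = LinearRegression() if ridge_alpha == 0 else Ridge(alpha=ridge_alpha)
    elif kind == "tree_ensemble":
        from sklearn.ensemble import RandomForestRegressor

        reg = RandomForestRegressor(n_estimators=60, random_state=seed, n_jobs=1)
    elif kind == "feedforward_net":
        from sklearn.neural_network import MLPRegressor

        reg = MLPRegressor(hidden_layer_sizes=(64, 32), max_iter=300, random_state=seed)
    else:  # boosted_trees
        try:
            from xgboost import XGBRegressor

            reg = XGBRegressor(n_estimators=100, max_depth=4, random_state=seed,
                               n_jobs=1, verbosity=0)
        except ImportError:
            from sklearn.ensemble import GradientBoostingRegressor

            reg = GradientBoostingRegressor(random_state=seed)
    reg.fit(xtr, y)
    return np.asarray(reg.predict(xte), float)


def fm_fewshot_benchmark(
    ds: ScreenDataset,
    fm,
    heldout_study: str,
    n_few_shots: Sequence[int] = (10, 50, 100, 200),
    repeats: int = 5,
    seed: int = 0,
    finetuned_factory: Callable | None = None,
    min_queries: int = 5,
) -> pd.DataFrame:
    """Per-sample few-shot Spearman on a held-out study.

    For each sample of the held-out study, each context size n and each
    repeat, a random n-measurement context is drawn, the remaining
    measurements are predicted, and the per-sample Spearman correlation is
    recorded for the foundation model, a context-mean baseline and (when
    `finetuned_factory(context)` is given) the fine-tuned variant. Samples
    with fewer than n + min_queries measurements are evaluated at their
    maximum feasible n and flagged."""
    from .fm import _sample_measurements

    held = ds.subset_studies([heldout_study])
    per_sample = _sample_measurements(held)
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        for n in n_few_shots:
            for sid, (drugs, doses, viab) in per_sample.items():
                total = len(drugs)
                n_eff = n
                flagged = False
                if total < n + min_queries:
                    n_eff = max(1, total - min_queries)
                    flagged = True
                    if n_eff < 1 or total - n_eff < 3:
                        continue
                perm = rng.permutation(total)
                ctx_i, qry_i = perm[:n_eff], perm[n_eff:]
                ctx = list(zip(drugs[ctx_i], doses[ctx_i], viab[ctx_i]))
                qry = list(zip(drugs[qry_i], doses[qry_i]))
                ytrue = viab[qry_i]
                if np.std(ytrue) == 0:
                    continue
                models = {"FM": fm.predict_query(ctx, qry)}
                models["context_mean"] = np.full(len(qry), viab[ctx_i].mean())
                if finetuned_factory is not None:
                    ft = finetuned_factory(ctx)
                    models["FM++"] = ft.predict_query(ctx, qry)
                for name, pred in models.items():
                    rho = (
                        0.0 if np.std(pred) == 0
                        else stats.spearmanr(ytrue, pred).statistic
                    )
                    rows.append(
                        {"study": heldout_study, "sample_id": sid, "repeat": rep,
                         "n_few_shots": n, "n_effective": n_eff, "flagged": flagged,
                         "model": name, "spearman": float(rho)}
                    )
    return pd.DataFrame(rows)


def integration_benefit(
    ds: ScreenDataset,
    model_factory: Callable[[ScreenDataset], object],
    exvivo_studies: Sequence[str],
    target_study: str,
    n_heldout_drugs: int = 12,
    seed: int = 0,
) -> dict:
    """Held-out ex vivo RMSE with vs without the non-ex-vivo studies.

    Whole drugs are held out of the target ex vivo study (each drug must also
    appear in at least one other ex vivo study so both arms can predict it).
    Returns the two median RMSEs, the per-curve improvement fraction, and a
    sign-test p-value."""
    rec = ds.records
    exvivo_mask = rec["study_id"].isin(exvivo_studies)
    target_drugs = sorted(set(rec.loc[rec["study_id"] == target_study, "drug_id"]))
    other_ev = rec.loc[exvivo_mask & (rec["study_id"] != target_study), "drug_id"]
    candidates = [d for d in target_drugs if d in set(other_ev)]
    rng = np.random.default_rng(seed)
    held = set(rng.choice(candidates, min(n_heldout_drugs, len(candidates)), replace=False))
    test_mask = (rec["study_id"] == target_study) & rec["drug_id"].isin(held)
    test = rec[test_mask]

    def errors(train_rec: pd.DataFrame) -> dict:
        model = model_factory(ScreenDataset(train_rec, samples=ds.samples, drugs=ds.drugs))
        out = {}
        for (st, sid, did), grp in test.groupby(["study_id", "sample_id", "drug_id"]):
            logc = np.log10(grp["concentration_uM"].to_numpy(float))
            try:
                yhat = model.predict(sid, did, logc)
            except KeyError:
                continue
            out[(st, sid, did)] = float(
                np.sqrt(np.mean((grp["viability"].to_numpy() - yhat) ** 2))
            )
        return out

    e_exvivo = errors(rec[~test_mask & exvivo_mask])
    e_joint = errors(rec[~test_mask])
    common = sorted(set(e_exvivo) & set(e_joint))
    if not common:
        raise ValidationError("no common predictable held-out curves")
    improved = sum(e_joint[k] < e_exvivo[k] for k in common)
    p = stats.binomtest(improved, len(common), 0.5, alternative="greater").pvalue
    return {
        "median_rmse_exvivo_only": float(np.median([e_exvivo[k] for k in common])),
        "median_rmse_with_celllines": float(np.median([e_joint[k] for k in common])),
        "frac_improved": improved / len(common),
        "n_curves": len(common),
        "p": float(p),
    }


def summarize_fewshot(bench: pd.DataFrame) -> pd.DataFrame:
    """Median per-sample Spearman per (model, n), with mean ± 2 sd over repeats."""
    per_rep = (
        bench.groupby(["model", "n_few_shots", "repeat"])["spearman"].median().reset_index()
    )
    out = per_rep.groupby(["model", "n_few_shots"])["spearman"].agg(["mean", "std", "count"])
    out["two_sd"] = 2 * out["std"].fillna(0.0)
    return out.reset_index()
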