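"""Few-shot transformer for dose-response prediction, with omics probes.

The model performs in-context regression: given a small labeled context of
(drug, dose, viability) triplets measured on one biological sample and a set
of unlabeled (drug, dose) queries, it predicts the query viabilities in a
single forward pass. Tokens are the concatenation of three sub-embeddings —
a drug dictionary embedding, a Fourier-feature embedding of log10 dose, and a
Fourier-feature embedding of viability (a learned placeholder for queries) —
so the token width is 3 × sub_embedding. Tokens carry no positional encoding:
context and query sets are exchangeable, and the attention mask lets context
tokens attend only to context while each query attends to the context and to
itself. Query representations from the final block go through a linear head.

Training is episodic: sample a biological sample, split its measurements into
context and query at a random context size, and minimize MSE on the query
viabilities. Fine-tuning (the "++" variant) copies the weights and takes a few
low-learning-rate epochs on a new study's few-shot records only.

Probes are deliberately simple: logistic regression (mutation status, AUROC)
and ridge regression (pathway activity, Pearson r) on extracted sample
embeddings, cross-validated.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Adam, Tensor, concat
from .errors import ConfigError, MultiscreenError, ValidationError
from .screen_data import ScreenDataset

OOV = "<oov>"


@dataclass(frozen=True)
class FMConfig:
    n_blocks: int = 8
    hidden: int = 384
    intermediate: int = 512
    n_heads: int = 8
    sub_embedding: int = 128
    n_fourier: int = 32
    context_range: tuple = (5, 100)
    query_size: int = 32
    batch_episodes: int = 8
    lr: float = 3e-3
    n_steps: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.hidden != 3 * self.sub_embedding:
            raise ConfigError("hidden must equal 3 * sub_embedding")
        if self.hidden % self.n_heads:
            raise ConfigError("n_heads must divide hidden")

    def with_(self, **kw) -> "FMConfig":
        return replace(self, **kw)

    @classmethod
    def paper(cls, **kw) -> "FMConfig":
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "FMConfig":
        """Small preset for CPU runs: 2 blocks, hidden 96 (sub-embedding 32)."""
        base = dict(n_blocks=2, hidden=96, intermediate=128, n_heads=4,
                    sub_embedding=32, n_fourier=16)
        base.update(kw)
        return cls(**base)


def _init_fourier(rng, n_fourier: int, sub: int) -> dict:
    freqs = np.logspace(-1, 1.2, n_fourier)  # log-spaced initial frequencies
    return {
        "freqs": Tensor(freqs, requires_grad=True),
        "W": Tensor(rng.normal(0, 1.0 / np.sqrt(2 * n_fourier), (2 * n_fourier, sub)),
                    requires_grad=True),
        "b": Tensor(np.zeros(sub), requires_grad=True),
    }


def fourier_embed(x, params: Mapping[str, Tensor]) -> Tensor:
    """Continuous-scalar embedding: learnable-frequency sin/cos features,
    linearly combined to the sub-embedding width."""
    arr = np.asarray(x, float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("fourier_embed requires finite inputs")
    xt = Tensor(arr.reshape(-1, 1))
    phase = xt * params["freqs"].reshape(1, -1)  # (n, F)
    s = _sin(phase)
    c = _cos(phase)
    feats = concat([s, c], axis=1)
    return feats @ params["W"] + params["b"]


def _sin(t: Tensor) -> Tensor:
    y = np.sin(t.data)
    return Tensor._make(y, (t,), lambda g: (g * np.cos(t.data),))


def _cos(t: Tensor) -> Tensor:
    y = np.cos(t.data)
    return Tensor._make(y, (t,), lambda g: (g * -np.sin(t.data),))


class FMModel:
    """Transformer weights + tokenizer dictionaries + Fourier parameters."""

    def __init__(self, cfg: FMConfig, drug_vocab: Sequence[str], seed: int | None = None):
        self.cfg = cfg
        self.drug_vocab = list(drug_vocab)
        self._drug_index = {d: i for i, d in enumerate(self.drug_vocab)}
        self.loss_trace: list = []
        self.trained_studies: list = []
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        sub, H, inter = cfg.sub_embedding, cfg.hidden, cfg.intermediate
        scale = 1.0 / np.sqrt(H)
        p: dict[str, Tensor] = {}
        p["drug_emb"] = Tensor(rng.normal(0, 0.5, (len(self.drug_vocab) + 1, sub)),
                               requires_grad=True)
        self.dose_fourier = _init_fourier(rng, cfg.n_fourier, sub)
        self.viab_fourier = _init_fourier(rng, cfg.n_fourier, sub)
        p["placeholder"] = Tensor(rng.normal(0, 0.5, (sub,)), requires_grad=True)
        for l in range(cfg.n_blocks):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{l}.{name}"] = Tensor(rng.normal(0, scale, (H, H)), requires_grad=True)
            p[f"{l}.ln1_g"] = Tensor(np.ones(H), requires_grad=True)
            p[f"{l}.ln1_b"] = Tensor(np.zeros(H), requires_grad=True)
            p[f"{l}.ln2_g"] = Tensor(np.ones(H), requires_grad=True)
            p[f"{l}.ln2_b"] = Tensor(np.zeros(H), requires_grad=True)
            p[f"{l}.W1"] = Tensor(rng.normal(0, scale, (H, inter)), requires_grad=True)
            p[f"{l}.b1"] = Tensor(np.zeros(inter), requires_grad=True)
            p[f"{l}.W2"] = Tensor(rng.normal(0, 1.0 / np.sqrt(inter), (inter, H)),
                                  requires_grad=True)
            p[f"{l}.b2"] = Tensor(np.zeros(H), requires_grad=True)
        p["lnf_g"] = Tensor(np.ones(H), requires_grad=True)
        p["lnf_b"] = Tensor(np.zeros(H), requires_grad=True)
        p["head_W"] = Tensor(rng.normal(0, scale, (H, 1)), requires_grad=True)
        p["head_b"] = Tensor(np.zeros(1), requires_grad=True)
        self.params = p

    # -- tokenization ------------------------------------------------------
    def drug_indices(self, drug_ids: Sequence[str]) -> np.ndarray:
        idx = np.empty(len(drug_ids), np.intp)
        oov = len(self.drug_vocab)
        unseen = set()
        for i, d in enumerate(drug_ids):
            j = self._drug_index.get(d, oov)
            if j == oov:
                unseen.add(d)
            idx[i] = j
        if unseen:
            warnings.warn(f"{len(unseen)} unseen drug ids mapped to OOV embedding")
        return idx

    def tokenize(self, context: Sequence[tuple], queries: Sequence[tuple]):
        """Token sequences for context triplets and query pairs.

        context: (drug_id, log10_dose, viability) triplets.
        queries: (drug_id, log10_dose) pairs. Returns (ctx, qry) Tensors of
        shape (n, hidden); the query viability slot holds the learned
        placeholder."""
        ctx = self._tokenize_arrays(
            self.drug_indices([c[0] for c in context]),
            np.array([c[1] for c in context], float),
            np.array([c[2] for c in context], float),
        )
        qry = self._tokenize_arrays(
            self.drug_indices([q[0] for q in queries]),
            np.array([q[1] for q in queries], float),
            None,
        )
        return ctx, qry

    def _tokenize_arrays(self, drug_idx, log10_dose, viability) -> Tensor:
        n = len(drug_idx)
        demb = self.params["drug_emb"].gather(drug_idx)
        dose = fourier_embed(log10_dose, self.dose_fourier)
        if viability is None:
            ones = np.ones((n, 1))
            viab = Tensor(ones) @ self.params["placeholder"].reshape(1, -1)
        else:
            viab = fourier_embed(viability, self.viab_fourier)
        return concat([demb, dose, viab], axis=1)

    # -- transformer -------------------------------------------------------
    def _layernorm(self, x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + 1e-5).sqrt() * g + b

    def _forward(self, ctx: Tensor, qry: Tensor, return_hidden: bool = False):
        """Masked joint stack over [context ‖ query].

        The additive mask permits attention to any context position and to the
        token's own position only among queries; context positions never see
        queries. No positional encodings, so predictions are invariant to
        permutations of either sequence."""
        cfg = self.cfg
        nc, nq = ctx.shape[0], qry.shape[0]
        n = nc + nq
        x = concat([ctx, qry], axis=0)
        allowed = np.zeros((n, n), bool)
        allowed[:, :nc] = True
        allowed[np.arange(n), np.arange(n)] = True
        allowed[:nc, nc:] = False
        mask = np.where(allowed, 0.0, -1e9)
        hd = cfg.hidden // cfg.n_heads
        for l in range(cfg.n_blocks):
            p = self.params
            h = self._layernorm(x, p[f"{l}.ln1_g"], p[f"{l}.ln1_b"])
            q = (h @ p[f"{l}.Wq"]).reshape(n, cfg.n_heads, hd).swapaxes(0, 1)
            k = (h @ p[f"{l}.Wk"]).reshape(n, cfg.n_heads, hd).swapaxes(0, 1)
            v = (h @ p[f"{l}.Wv"]).reshape(n, cfg.n_heads, hd).swapaxes(0, 1)
            scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(hd)) + mask
            att = scores.softmax(axis=-1) @ v  # (heads, n, hd)
            att = att.swapaxes(0, 1).reshape(n, cfg.hidden)
            x = x + att @ p[f"{l}.Wo"]
            h2 = self._layernorm(x, p[f"{l}.ln2_g"], p[f"{l}.ln2_b"])
            x = x + (h2 @ p[f"{l}.W1"] + p[f"{l}.b1"]).gelu() @ p[f"{l}.W2"] + p[f"{l}.b2"]
        xf = self._layernorm(x, self.params["lnf_g"], self.params["lnf_b"])
        preds = xf[np.arange(nc, n)] @ self.params["head_W"] + self.params["head_b"]
        if return_hidden:
            return preds.reshape(nq), xf
        return preds.reshape(nq)

    def predict_query(self, context: Sequence[tuple], queries: Sequence[tuple]) -> np.ndarray:
        """Predicted viability per query, clipped to [0, 2].

        An empty context is allowed (prior-like predictions, flagged)."""
        if len(queries) == 0:
            return np.zeros(0)
        if len(context) == 0:
            warnings.warn("empty context: predictions are prior-like")
            context = []
        ctx, qry = self.tokenize(context, queries)
        out = self._forward(ctx, qry)
        return np.clip(out.data, 0.0, 2.0)

    def extract_sample_embedding(self, context: Sequence[tuple]) -> np.ndarray:
        """Mean-pooled final-block context-token representation (length = hidden)."""
        if len(context) == 0:
            raise ValidationError("embedding requires a non-empty context")
        ctx, qry = self.tokenize(context, [(context[0][0], context[0][1])])
        _, hidden = self._forward(ctx, qry, return_hidden=True)
        return hidden.data[: len(context)].mean(axis=0)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": {**self.cfg.__dict__, "context_range": list(self.cfg.context_range)},
            "drug_vocab": self.drug_vocab,
            "trained_studies": self.trained_studies,
        }
        (path / "metadata.json").write_text(json.dumps(meta))
        arrays = {k.replace(".", "__"): t.data for k, t in self.params.items()}
        for grp, prefix in ((self.dose_fourier, "dosef"), (self.viab_fourier, "viabf")):
            for k, t in grp.items():
                arrays[f"{prefix}__{k}"] = t.data
        arrays["loss_trace"] = np.asarray(self.loss_trace, float)
        np.savez(path / "arrays.npz", **arrays)

    @classmethod
    def load(cls, path) -> "FMModel":
        path = Path(path)
        try:
            meta = json.loads((path / "metadata.json").read_text())
            arrays = np.load(path / "arrays.npz")
        except Exception as exc:
            raise MultiscreenError(f"cannot load FM from {path}: {exc}") from exc
        cfgd = dict(meta["config"])
        cfgd["context_range"] = tuple(cfgd["context_range"])
        model = cls(FMConfig(**cfgd), meta["drug_vocab"])
        for k in model.params:
            model.params[k].data = arrays[k.replace(".", "__")].copy()
        for grp, prefix in ((model.dose_fourier, "dosef"), (model.viab_fourier, "viabf")):
            for k in grp:
                grp[k].data = arrays[f"{prefix}__{k}"].copy()
        model.loss_trace = arrays["loss_trace"].tolist()
        model.trained_studies = meta["trained_studies"]
        return model

    def _all_params(self):
        return list(self.params.values()) + list(self.dose_fourier.values()) + list(
            self.viab_fourier.values()
        )


def _sample_measurements(ds: ScreenDataset) -> dict[str, np.ndarray]:
    """Per-sample (drug_id, log10 dose, viability) arrays."""
    out = {}
    for sid, grp in ds.records.groupby("sample_id"):
        out[sid] = (
            grp["drug_id"].to_numpy(),
            np.log10(grp["concentration_uM"].to_numpy(float)),
            grp["viability"].to_numpy(float),
        )
    return out


def train_fm(
    ds: ScreenDataset,
    cfg: FMConfig = FMConfig(),
    exclude_studies: Sequence[str] = (),
    verbose: bool = False,
) -> FMModel:
    """Episodic training on context/query splits of per-sample measurements."""
    train_ds = ds.subset_studies([s for s in ds.study_ids if s not in set(exclude_studies)])
    if not train_ds.study_ids:
        raise ValidationError("no studies left to train on")
    model = FMModel(cfg, drug_vocab=sorted(set(train_ds.records["drug_id"])))
    model.trained_studies = train_ds.study_ids
    per_sample = _sample_measurements(train_ds)
    eligible = [s for s, (d, _, _) in per_sample.items() if len(d) >= 4]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model._all_params(), lr=cfg.lr)
    for step in range(cfg.n_steps):
        opt.zero_grad()
        losses = []
        nc_lo, nc_hi = cfg.context_range
        for _ in range(cfg.batch_episodes):
            sid = eligible[int(rng.integers(len(eligible)))]
            drugs, doses, viab = per_sample[sid]
            n = len(drugs)
            nc = int(rng.integers(nc_lo, min(nc_hi, n - 1) + 1)) if n - 1 > nc_lo else max(1, n // 2)
            nc = min(nc, n - 1)
            perm = rng.permutation(n)
            ctx_i = perm[:nc]
            qry_i = perm[nc: nc + min(cfg.query_size, n - nc)]
            ctx = list(zip(drugs[ctx_i], doses[ctx_i], viab[ctx_i]))
            qry = list(zip(drugs[qry_i], doses[qry_i]))
            ct, qt = model.tokenize(ctx, qry)
            pred = model._forward(ct, qt)
            err = pred - Tensor(viab[qry_i])
            losses.append((err * err).mean())
        loss = losses[0]
        for extra in losses[1:]:
            loss = loss + extra
        loss = loss * (1.0 / len(losses))
        if not np.isfinite(loss.data):
            raise MultiscreenError(f"FM training diverged at step {step}")
        model.loss_trace.append(float(loss.data))
        loss.backward()
        opt.step()
        if verbose and step % 50 == 0:
            print(f"step {step}: loss {float(loss.data):.4f}")
    return model


def finetune(
    model: FMModel,
    fewshot: Sequence[tuple],
    n_epochs: int = 20,
    lr: float = 3e-4,
    seed: int = 0,
) -> FMModel:
    """FM++: copy the model, take a few low-LR steps on the few-shot records.

    `fewshot` is (drug_id, log10_dose, viability) triplets from the new
    sample/study. The original model is left untouched."""
    if len(fewshot) == 0:
        raise ValidationError("finetune requires at least one few-shot record")
    new = copy.deepcopy(model)
    if n_epochs == 0:
        return new
    rng = np.random.default_rng(seed)
    opt = Adam(new._all_params(), lr=lr)
    arr = list(fewshot)
    n = len(arr)
    for _ in range(n_epochs):
        opt.zero_grad()
        perm = rng.permutation(n)
        nc = max(1, n // 2)
        ctx = [arr[i] for i in perm[:nc]]
        qry_full = [arr[i] for i in perm[nc:]] or [arr[perm[0]]]
        qt_pairs = [(d, x) for d, x, _ in qry_full]
        y = np.array([v for _, _, v in qry_full])
        ct, qt = new.tokenize(ctx, qt_pairs)
        pred = new._forward(ct, qt)
        err = pred - Tensor(y)
        loss = (err * err).mean()
        loss.backward()
        opt.step()
    return new


# -- probes ----------------------------------------------------------------

@dataclass
class ProbeResult:
    target: str
    metric: str               # "auroc" | "pearson_r"
    value: float
    per_fold: list = field(default_factory=list)
    n_few_shots: int | None = None
    skipped: bool = False


def probe_mutation(
    embeddings: np.ndarray, labels: Sequence[int], folds: int = 5, seed: int = 0,
    target: str = "", n_few_shots: int | None = None,
) -> ProbeResult:
    """Cross-validated logistic probe; mean AUROC over stratified folds."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, int)
    x = np.asarray(embeddings, float)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < folds:
        return ProbeResult(target=target, metric="auroc", value=np.nan, skipped=True)
    aurocs = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(x, y):
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(x[tr], y[tr])
        aurocs.append(roc_auc_score(y[te], clf.predict_proba(x[te])[:, 1]))
    return ProbeResult(target=target, metric="auroc", value=float(np.mean(aurocs)),
                       per_fold=list(map(float, aurocs)), n_few_shots=n_few_shots)


def probe_pathway(
    embeddings: np.ndarray, scores: Sequence[float], folds: int = 5, seed: int = 0,
    target: str = "", n_few_shots: int | None = None,
) -> ProbeResult:
    """Cross-validated ridge probe; mean per-fold Pearson r, inner-CV alpha."""
    from sklearn.linear_model import RidgeCV
    from sklearn.model_selection import KFold

    y = np.asarray(scores, float)
    x = np.asarray(embeddings, float)
    if np.std(y) == 0:
        return ProbeResult(target=target, metric="pearson_r", value=np.nan, skipped=True)
    rs = []
    for tr, te in KFold(n_splits=folds, shuffle=True, random_state=seed).split(x):
        reg = RidgeCV(alphas=np.logspace(-3, 3, 13))
        reg.fit(x[tr], y[tr])
        pred = reg.predict(x[te])
        if np.std(pred) == 0 or np.std(y[te]) == 0:
            rs.append(0.0)
        else:
            rs.append(stats.pearsonr(y[te], pred)[0])
    return ProbeResult(target=target, metric="pearson_r", value=float(np.mean(rs)),
                       per_fold=list(map(float, rs)), n_few_shots=n_few_shots)


def read_gmt(path) -> dict[str, list]:
    """Gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in gene_sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def pathway_score(
    expression: pd.DataFrame, gene_set: Sequence[str], allow_single: bool = False
) -> pd.Series:
    """First principal component of member genes as pathway activity.

    Expression is genes × samples, raw scale. Pipeline: library-size normalize
    per sample, log(1 + x), standardize each gene, PC1 across member genes;
    the sign is oriented so the mean gene loading is positive."""
    expr = expression.loc[~expression.index.duplicated()]
    members = [g for g in dict.fromkeys(gene_set) if g in expr.index]
    if len(members) < 2 and not allow_single:
        raise ValidationError(f"only {len(members)} member genes present (need >= 2)")
    if len(members) == 0:
        raise ValidationError("no member genes present")
    x = expr.to_numpy(float)
    libsize = x.sum(axis=0)
    norm = x / libsize * np.median(libsize)
    logx = np.log1p(norm)
    sd = logx.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    standardized = (logx - logx.mean(axis=1, keepdims=True)) / sd
    zd = pd.DataFrame(standardized, index=expr.index, columns=expr.columns)
    sub = zd.loc[members].to_numpy()  # (m, n_samples)
    if len(members) == 1:
        return pd.Series(sub[0], index=expr.columns)
    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    score = s[0] * vt[0]
    if u[:, 0].mean() < 0:
        score = -score
    return pd.Series(score, index=expr.columns)


def joint_consistency(
    readouts: Mapping[str, Sequence[np.ndarray]],
    mutant_mask: np.ndarray,
    directions: Mapping[str, str],
) -> dict:
    """Fisher-combined one-sided Mann–Whitney tests across few-shot repeats.

    `readouts` maps a readout name (e.g. "mutation_logit", "pathway_score",
    "predicted_auc") to one value-array per repeat, aligned with
    `mutant_mask`. `directions[name]` ("greater"/"less") states the
    hypothesized direction for the mutant group."""
    mutant_mask = np.asarray(mutant_mask, bool)
    if mutant_mask.all() or not mutant_mask.any():
        raise ValidationError("both mutant and wild-type groups must be non-empty")
    out = {}
    for name, repeats in readouts.items():
        ps = []
        for values in repeats:
            v = np.asarray(values, float)
            res = stats.mannwhitneyu(
                v[mutant_mask], v[~mutant_mask], alternative=directions.get(name, "greater")
            )
            ps.append(float(res.pvalue))
        from .differential import fisher_method

        combined, chi2 = fisher_method(ps)
        out[name] = {"p_combined": combined, "chi2": chi2, "per_repeat_p": ps}
    return out
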