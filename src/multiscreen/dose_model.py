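"""Contrastive Bayesian tensor factorization of dose-response screens.

Each sample i carries an embedding v_i ∈ R^d; each drug j carries one
embedding per dose-grid point, u_j^(1..K) ∈ R^d. The latent curve on drug j's
log10-concentration grid is a cumulative product of retention fractions

    m_0 = 1,   m_k = m_{k-1} * sigmoid(u_j^(k) · v_i),   k = 1..K,

so every inferred curve is monotone non-increasing and lies in (0, 1];
concentrations between grid points are linearly interpolated in log10 space
and extrapolated flat beyond the grid ends. Observed viabilities get a
Gaussian likelihood with a learned per-study noise scale (so values above the
(0, 1] model mean are absorbed by observation noise).

Inference is mean-field Gaussian variational inference with the
reparameterization trick; the training objective is

    -ELBO + λ_sample · L_contrast(sample embeddings | primary site)
          + λ_drug   · L_contrast(concatenated drug embeddings | first mechanism)

where L_contrast is a supervised contrastive loss over cosine similarities of
posterior means. Posterior uncertainty is exposed by drawing S joint samples
of (v, u) and summarizing the resulting curve ensemble.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .errors import ConfigError, MultiscreenError, ValidationError
from .screen_data import DoseGrid, ScreenDataset, build_dose_grids

FORMAT_VERSION = (1, 0)


@dataclass(frozen=True)
class ModelConfig:
    d: int = 32
    K: int = 10
    prior_sd: float = 1.0
    lambda_sample: float = 0.1
    lambda_drug: float = 0.1
    temperature: float = 0.5
    n_posterior_samples: int = 50
    lr: float = 0.05
    n_iters: int = 800
    init_scale: float = 0.05
    init_logsd: float = -3.0
    seed: int = 0

    def __post_init__(self):
        if self.d < 1:
            raise ConfigError("embedding dimension d must be >= 1")
        if self.lambda_sample < 0 or self.lambda_drug < 0:
            raise ConfigError("contrastive weights must be >= 0")
        if self.n_posterior_samples < 1:
            raise ConfigError("n_posterior_samples must be >= 1")

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


def curve_from_embeddings(
    v: np.ndarray,
    u: np.ndarray,
    grid_log10: np.ndarray,
    query_logconcs: np.ndarray,
) -> np.ndarray:
    """Deterministic curve for one (sample, drug) pair.

    Parameters
    ----------
    v : (d,) sample embedding
    u : (K, d) per-grid-point drug embeddings
    grid_log10 : (K,) strictly increasing log10 concentrations
    query_logconcs : query log10 concentrations (clamped to grid ends)
    """
    v = np.asarray(v, float)
    u = np.asarray(u, float)
    if u.shape[1] != v.shape[0]:
        raise ValidationError(
            f"dimension mismatch: v has d={v.shape[0]}, u has d={u.shape[1]}"
        )
    scores = u @ v  # (K,)
    # log sigmoid, numerically stable
    logsig = -np.logaddexp(0.0, -scores)
    m = np.exp(np.cumsum(logsig))  # (K,) grid viabilities
    grid = DoseGrid("query", np.asarray(grid_log10, float))
    lo, w = grid.interp_weights(np.asarray(query_logconcs, float))
    return (1.0 - w) * m[lo] + w * m[lo + 1]


def contrastive_penalty(
    embeddings: np.ndarray, group_labels: Sequence, temperature: float = 0.5
) -> float:
    """Supervised contrastive loss over cosine similarities (numpy version).

    Per anchor a with positives P(a) (same label, excluding a):
    -log( sum_{p in P(a)} e^{sim(a,p)/T} / sum_{b != a} e^{sim(a,b)/T} ),
    averaged over anchors that have at least one positive. Returns 0.0 (with a
    warning) when no group has two members.
    """
    t = _contrastive_tensor(Tensor(np.asarray(embeddings, float)), group_labels, temperature)
    return float(t.data) if isinstance(t, Tensor) else float(t)


def _contrastive_tensor(emb: Tensor, labels: Sequence, temperature: float):
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    pos_mask = (labels[:, None] == labels[None, :]) & ~np.eye(n, dtype=bool)
    valid = pos_mask.any(axis=1)
    if len(set(labels)) < 2 or not valid.any():
        warnings.warn(
            "contrastive penalty needs >= 2 groups with >= 2 members; returning 0"
        )
        return Tensor(np.zeros(()))
    norm = (emb * emb).sum(axis=1, keepdims=True).clip_min(1e-12).sqrt()
    e = emb / norm
    sim = e @ e.swapaxes(0, 1) * (1.0 / temperature)
    expsim = sim.exp()
    off = ~np.eye(n, dtype=bool)
    num = (expsim * pos_mask.astype(float)).sum(axis=1)
    den = (expsim * off.astype(float)).sum(axis=1)
    per_anchor = den.log() - num.clip_min(1e-300).log()
    return (per_anchor * valid.astype(float)).sum() * (1.0 / valid.sum())


@dataclass
class _Design:
    """Index arrays linking records to pairs, grids and studies."""

    sample_ids: list
    drug_ids: list
    study_ids: list
    pair_sample: np.ndarray  # (P,)
    pair_drug: np.ndarray    # (P,)
    rec_pair: np.ndarray     # (N,)
    rec_klo: np.ndarray      # (N,)
    rec_w: np.ndarray        # (N,)
    rec_study: np.ndarray    # (N,)
    y: np.ndarray            # (N,)


def _build_design(ds: ScreenDataset, grids: Mapping[str, DoseGrid]) -> _Design:
    sample_ids = sorted(ds.samples)
    drug_ids = sorted(set(ds.records["drug_id"]))
    study_ids = ds.study_ids
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    d_idx = {d: j for j, d in enumerate(drug_ids)}
    st_idx = {s: k for k, s in enumerate(study_ids)}

    rec = ds.records
    si = rec["sample_id"].map(s_idx).to_numpy(np.intp)
    di = rec["drug_id"].map(d_idx).to_numpy(np.intp)
    sti = rec["study_id"].map(st_idx).to_numpy(np.intp)
    logc = np.log10(rec["concentration_uM"].to_numpy(float))
    y = rec["viability"].to_numpy(float)

    pair_key = si.astype(np.int64) * len(drug_ids) + di
    uniq, rec_pair = np.unique(pair_key, return_inverse=True)
    pair_sample = (uniq // len(drug_ids)).astype(np.intp)
    pair_drug = (uniq % len(drug_ids)).astype(np.intp)

    klo = np.empty(len(rec), np.intp)
    w = np.empty(len(rec), float)
    for j, did in enumerate(drug_ids):
        mask = di == j
        if mask.any():
            klo[mask], w[mask] = grids[did].interp_weights(logc[mask])
    return _Design(sample_ids, drug_ids, study_ids, pair_sample, pair_drug,
                   rec_pair, klo, w, sti, y)


def _gaussian_kl(mean: Tensor, logsd: Tensor, prior_sd: float) -> Tensor:
    """KL( N(mean, sd^2) || N(0, prior_sd^2) ), summed over all entries."""
    var = (logsd * 2.0).exp()
    return (
        0.5 * ((var + mean * mean) * (1.0 / prior_sd**2)) - logsd - 0.5 + np.log(prior_sd)
    ).sum()


class FittedDoseModel:
    """Variational posterior over sample/drug embeddings plus dose grids."""

    def __init__(self, config: ModelConfig, design: _Design,
                 grids: Mapping[str, DoseGrid], params: dict,
                 sample_labels: Sequence, drug_labels: Sequence,
                 elbo_trace: np.ndarray):
        self.config = config
        self.grids = dict(grids)
        self.sample_ids = list(design.sample_ids)
        self.drug_ids = list(design.drug_ids)
        self.study_ids = list(design.study_ids)
        self.sample_labels = list(sample_labels)
        self.drug_labels = list(drug_labels)
        self.v_mean = params["v_mean"]
        self.v_logsd = params["v_logsd"]
        self.u_mean = params["u_mean"]
        self.u_logsd = params["u_logsd"]
        self.noise_logsd = params["noise_logsd"]
        self.elbo_trace = np.asarray(elbo_trace)
        self._design = design

    # -- indices -----------------------------------------------------------
    def _si(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def _di(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug_id {drug_id!r}") from None

    @property
    def observed_pairs(self) -> set:
        d = self._design
        return {
            (self.sample_ids[i], self.drug_ids[j])
            for i, j in zip(d.pair_sample, d.pair_drug)
        }

    def noise_sd(self, study_id: str) -> float:
        return float(np.exp(self.noise_logsd[self.study_ids.index(study_id)]))

    # -- prediction --------------------------------------------------------
    def posterior_curve_draws(
        self, sample_id: str, drug_id: str, query_logconcs=None,
        S: int | None = None, rng: np.random.Generator | None = None,
        v_override: tuple | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(S, Q) matrix of posterior curve draws and the query grid used.

        Each draw is individually monotone non-increasing. `v_override`
        optionally supplies an external (mean, sd) sample posterior (used for
        pilot-embedded new samples)."""
        S = S or self.config.n_posterior_samples
        rng = rng or np.random.default_rng(self.config.seed + 12345)
        j = self._di(drug_id)
        grid = self.grids[drug_id].log10_points
        q = grid if query_logconcs is None else np.asarray(query_logconcs, float)
        if v_override is None:
            i = self._si(sample_id)
            vm, vs = self.v_mean[i], np.exp(self.v_logsd[i])
        else:
            vm, vs = v_override
        um, us = self.u_mean[j], np.exp(self.u_logsd[j])
        draws = np.empty((S, len(q)))
        for s in range(S):
            v = vm + vs * rng.normal(size=vm.shape)
            u = um + us * rng.normal(size=um.shape)
            draws[s] = curve_from_embeddings(v, u, grid, q)
        return draws, q

    def posterior_grid_draw_matrix(
        self, S: int | None = None, seed: int | None = None,
        sample_ids: Sequence[str] | None = None,
        drug_ids: Sequence[str] | None = None,
    ):
        """Joint posterior curve draws over a samples × drugs block.

        Returns (draws, sample_ids, drug_ids) where draws has shape
        (S, n_samples, n_drugs, K) on each drug's own grid. One joint draw of
        all embeddings is shared across the block per posterior sample, so
        cross-pair structure is coherent."""
        S = S or self.config.n_posterior_samples
        rng = np.random.default_rng(self.config.seed + 999 if seed is None else seed)
        sample_ids = list(sample_ids if sample_ids is not None else self.sample_ids)
        drug_ids = list(drug_ids if drug_ids is not None else self.drug_ids)
        si = np.array([self._si(s) for s in sample_ids], np.intp)
        di = np.array([self._di(d) for d in drug_ids], np.intp)
        K = self.u_mean.shape[1]
        draws = np.empty((S, len(si), len(di), K))
        v_sd = np.exp(self.v_logsd)
        u_sd = np.exp(self.u_logsd)
        for s in range(S):
            v = self.v_mean + v_sd * rng.normal(size=self.v_mean.shape)
            u = self.u_mean + u_sd * rng.normal(size=self.u_mean.shape)
            vs = v[si]  # (n_s, d)
            for jj, j in enumerate(di):
                scores = vs @ u[j].T  # (n_s, K)
                logsig = -np.logaddexp(0.0, -scores)
                draws[s, :, jj, :] = np.exp(np.cumsum(logsig, axis=1))
        return draws, sample_ids, drug_ids

    def impute_curves(
        self, sample_ids: Sequence[str], drug_ids: Sequence[str],
        S: int | None = None, seed: int | None = None,
    ) -> dict:
        """Posterior mean curves with pointwise central 90% bands.

        Returns {(sample_id, drug_id): ImputedCurve} for the cross product of
        the given ids, on each drug's dose grid."""
        rng = np.random.default_rng(self.config.seed + 999 if seed is None else seed)
        out = {}
        for did in drug_ids:
            for sid in sample_ids:
                draws, q = self.posterior_curve_draws(sid, did, S=S, rng=rng)
                out[(sid, did)] = ImputedCurve(
                    sample_id=sid, drug_id=did, grid_log10=q,
                    mean=draws.mean(axis=0),
                    lo=np.quantile(draws, 0.05, axis=0),
                    hi=np.quantile(draws, 0.95, axis=0),
                    observed=(sid, did) in self.observed_pairs,
                )
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": list(FORMAT_VERSION),
            "config": asdict(self.config),
            "sample_ids": self.sample_ids,
            "drug_ids": self.drug_ids,
            "study_ids": self.study_ids,
            "sample_labels": self.sample_labels,
            "drug_labels": self.drug_labels,
            "grids": {d: g.log10_points.tolist() for d, g in self.grids.items()},
        }
        (path / "metadata.json").write_text(json.dumps(meta))
        np.savez(
            path / "arrays.npz",
            v_mean=self.v_mean, v_logsd=self.v_logsd,
            u_mean=self.u_mean, u_logsd=self.u_logsd,
            noise_logsd=self.noise_logsd, elbo_trace=self.elbo_trace,
            pair_sample=self._design.pair_sample,
            pair_drug=self._design.pair_drug,
        )

    @classmethod
    def load(cls, path) -> "FittedDoseModel":
        path = Path(path)
        try:
            meta = json.loads((path / "metadata.json").read_text())
            arrays = np.load(path / "arrays.npz")
        except Exception as exc:  # corrupted or missing
            raise MultiscreenError(f"cannot load model from {path}: {exc}") from exc
        major, minor = meta.get("format_version", (0, 0))
        if major != FORMAT_VERSION[0]:
            raise MultiscreenError(
                f"incompatible model format {major}.{minor}; expected {FORMAT_VERSION[0]}.x"
            )
        if minor != FORMAT_VERSION[1]:
            warnings.warn(f"loading model with minor format version {major}.{minor}")
        cfg = ModelConfig(**meta["config"])
        design = _Design(
            sample_ids=meta["sample_ids"], drug_ids=meta["drug_ids"],
            study_ids=meta["study_ids"],
            pair_sample=arrays["pair_sample"], pair_drug=arrays["pair_drug"],
            rec_pair=np.zeros(0, np.intp), rec_klo=np.zeros(0, np.intp),
            rec_w=np.zeros(0), rec_study=np.zeros(0, np.intp), y=np.zeros(0),
        )
        grids = {d: DoseGrid(d, np.array(pts)) for d, pts in meta["grids"].items()}
        params = {k: arrays[k] for k in ("v_mean", "v_logsd", "u_mean", "u_logsd", "noise_logsd")}
        return cls(cfg, design, grids, params, meta["sample_labels"],
                   meta["drug_labels"], arrays["elbo_trace"])


@dataclass
class ImputedCurve:
    sample_id: str
    drug_id: str
    grid_log10: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    observed: bool = False

    @property
    def band_width(self) -> float:
        return float(np.mean(self.hi - self.lo))


def _forward_nll(params, design: _Design, eps_v, eps_u):
    """Gaussian negative log likelihood of all records for one joint draw."""
    v = params["v_mean"] + (params["v_logsd"].exp() * eps_v)
    u = params["u_mean"] + (params["u_logsd"].exp() * eps_u)
    P = len(design.pair_sample)
    d = v.shape[1]
    vs = v.gather(design.pair_sample).reshape(P, 1, d)
    us = u.gather(design.pair_drug)
    scores = (us * vs).sum(axis=2)                      # (P, K)
    logm = (-((-scores).softplus())).cumsum(axis=1)     # log cumulative retention
    m = logm.exp()
    m_lo = m[(design.rec_pair, design.rec_klo)]
    m_hi = m[(design.rec_pair, design.rec_klo + 1)]
    pred = m_lo * (1.0 - design.rec_w) + m_hi * design.rec_w
    log_sd = params["noise_logsd"].gather(design.rec_study)
    resid = (Tensor(design.y) - pred) * (-log_sd).exp()
    nll = (resid * resid * 0.5 + log_sd).sum() + 0.5 * np.log(2 * np.pi) * len(design.y)
    return nll, pred


def elbo(
    ds: ScreenDataset,
    model: "FittedDoseModel",
    mc_samples: int = 10,
    seed: int = 0,
) -> float:
    """Monte-Carlo ELBO of `ds` under the model's posterior (diagnostic)."""
    design = _build_design(ds, model.grids)
    # remap studies/ids onto the model's index space
    params = {
        "v_mean": Tensor(model.v_mean), "v_logsd": Tensor(model.v_logsd),
        "u_mean": Tensor(model.u_mean), "u_logsd": Tensor(model.u_logsd),
        "noise_logsd": Tensor(model.noise_logsd),
    }
    rng = np.random.default_rng(seed)
    lik = 0.0
    for _ in range(mc_samples):
        eps_v = rng.normal(size=model.v_mean.shape)
        eps_u = rng.normal(size=model.u_mean.shape)
        nll, _ = _forward_nll(params, design, eps_v, eps_u)
        lik += -float(nll.data)
    lik /= mc_samples
    kl = float(
        (_gaussian_kl(params["v_mean"], params["v_logsd"], model.config.prior_sd)
         + _gaussian_kl(params["u_mean"], params["u_logsd"], model.config.prior_sd)).data
    )
    value = lik - kl
    if not np.isfinite(value):
        raise MultiscreenError(
            f"non-finite ELBO (likelihood={lik}, kl={kl}); check noise/scale parameters"
        )
    return value


def fit(
    ds: ScreenDataset,
    cfg: ModelConfig = ModelConfig(),
    grids: Mapping[str, DoseGrid] | None = None,
    verbose: bool = False,
) -> FittedDoseModel:
    """Fit the variational model by Adam on the reparameterized objective.

    Sample contrastive groups come from primary_site; drug groups from each
    drug's first-listed mechanism. Unlabeled entities are excluded from the
    penalty but not the likelihood.
    """
    if grids is None:
        grids = build_dose_grids(ds, K=cfg.K)
    design = _build_design(ds, grids)
    n_s, n_d = len(design.sample_ids), len(design.drug_ids)
    K = next(iter(grids.values())).K
    rng = np.random.default_rng(cfg.seed)

    params = {
        "v_mean": Tensor(rng.normal(0, cfg.init_scale, (n_s, cfg.d)), requires_grad=True),
        "v_logsd": Tensor(np.full((n_s, cfg.d), cfg.init_logsd), requires_grad=True),
        "u_mean": Tensor(rng.normal(0, cfg.init_scale, (n_d, K, cfg.d)), requires_grad=True),
        "u_logsd": Tensor(np.full((n_d, K, cfg.d), cfg.init_logsd), requires_grad=True),
        "noise_logsd": Tensor(np.full(len(design.study_ids), np.log(0.1)), requires_grad=True),
    }

    sample_labels = [ds.samples[s].primary_site or None for s in design.sample_ids]
    drug_labels = [ds.drugs[d].first_mechanism for d in design.drug_ids]
    s_mask = np.array([l is not None for l in sample_labels])
    d_mask = np.array([l is not None for l in drug_labels])

    opt = Adam(params.values(), lr=cfg.lr)
    trace = np.empty(cfg.n_iters)
    best = None
    for it in range(cfg.n_iters):
        opt.zero_grad()
        eps_v = rng.normal(size=(n_s, cfg.d))
        eps_u = rng.normal(size=(n_d, K, cfg.d))
        nll, _ = _forward_nll(params, design, eps_v, eps_u)
        kl = _gaussian_kl(params["v_mean"], params["v_logsd"], cfg.prior_sd) + _gaussian_kl(
            params["u_mean"], params["u_logsd"], cfg.prior_sd
        )
        loss = nll + kl
        if cfg.lambda_sample > 0 and s_mask.sum() >= 2:
            emb = params["v_mean"][np.where(s_mask)[0]]
            labels = [l for l in sample_labels if l is not None]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                loss = loss + cfg.lambda_sample * _contrastive_tensor(emb, labels, cfg.temperature)
        if cfg.lambda_drug > 0 and d_mask.sum() >= 2:
            emb = params["u_mean"][np.where(d_mask)[0]].reshape(int(d_mask.sum()), K * cfg.d)
            labels = [l for l in drug_labels if l is not None]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                loss = loss + cfg.lambda_drug * _contrastive_tensor(emb, labels, cfg.temperature)
        if not np.isfinite(loss.data):
            if best is None:
                raise MultiscreenError("training diverged with no good checkpoint")
            warnings.warn(f"divergence at iter {it}; restoring last good checkpoint")
            for k, v in best.items():
                params[k].data = v
            break
        trace[it] = -float(loss.data)
        loss.backward()
        opt.step()
        if it % 50 == 0:
            best = {k: p.data.copy() for k, p in params.items()}
            if verbose:
                print(f"iter {it}: loss {float(loss.data):.1f}")

    final = {k: p.data.copy() for k, p in params.items()}
    return FittedDoseModel(cfg, design, grids, final, sample_labels, drug_labels, trace)


def embed_new_sample(
    model: FittedDoseModel,
    pilot: Sequence[tuple],
    n_iters: int = 400,
    lr: float = 0.05,
    seed: int = 0,
):
    """Posterior for a new sample from a small pilot screen.

    `pilot` is a sequence of (drug_id, concentration_uM, viability) triples on
    drugs known to the model. Only the new sample's embedding posterior is
    optimized; all drug parameters stay frozen at their posterior means.
    Returns (mean, sd) arrays of shape (d,).
    """
    if len(pilot) == 0:
        raise ValidationError("empty pilot screen")
    d = model.config.d
    rows = []
    for drug_id, conc, viab in pilot:
        j = model._di(drug_id)  # raises KeyError on unknown drug
        grid = model.grids[drug_id]
        lo, w = grid.interp_weights(np.log10([conc]))
        rows.append((j, int(lo[0]), float(w[0]), float(viab)))
    ju = np.array([r[0] for r in rows], np.intp)
    klo = np.array([r[1] for r in rows], np.intp)
    w = np.array([r[2] for r in rows])
    y = np.array([r[3] for r in rows])
    u_mean = model.u_mean[ju]  # (n_pilot, K, d) frozen
    noise_sd = float(np.exp(model.noise_logsd).mean())

    rng = np.random.default_rng(seed)
    vm = Tensor(np.zeros(d), requires_grad=True)
    vls = Tensor(np.full(d, -1.0), requires_grad=True)
    opt = Adam([vm, vls], lr=lr)
    uT = Tensor(u_mean)
    for _ in range(n_iters):
        opt.zero_grad()
        eps = rng.normal(size=d)
        v = vm + vls.exp() * eps
        scores = (uT * v.reshape(1, 1, d)).sum(axis=2)  # (n_pilot, K)
        m = ((-((-scores).softplus())).cumsum(axis=1)).exp()
        idx = np.arange(len(rows))
        pred = m[(idx, klo)] * (1.0 - w) + m[(idx, klo + 1)] * w
        resid = (Tensor(y) - pred) * (1.0 / noise_sd)
        nll = (resid * resid * 0.5).sum()
        kl = _gaussian_kl(vm, vls, model.config.prior_sd)
        loss = nll + kl
        loss.backward()
        opt.step()
    return vm.data.copy(), np.exp(vls.data.copy())
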