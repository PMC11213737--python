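"""Generative density models over control representations.

The distribution p(z) of latent representations from normal-appearing lung
is modeled either by a Gaussian mixture fitted with EM or by an affine
coupling normalizing flow. Both expose ``log_prob``; the patch anomaly
score is its negation, s(x) = -log p(f(x)), so low likelihood under the
control density reads as high anomaly.

The GMM is fitted from a k-means initialization with multiple restarts,
keeping the restart with the best final log-likelihood; the per-iteration
total log-likelihood trace is recorded (EM guarantees it non-decreasing).
Diagonal covariances with a variance floor are the default — robust on
moderate-dimensional representations with desk-scale sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .nn.autodiff import Adam, Tensor
from .nn.layers import MLP
from .types import AnomalyScore, Representation

__all__ = [
    "GMMModel",
    "FlowModel",
    "fit_gmm",
    "gmm_log_prob",
    "select_k_bic",
    "init_flow",
    "fit_flow",
    "flow_log_prob",
    "anomaly_score",
    "score_representations",
    "save_density",
    "load_density",
]

_LOG_2PI = np.log(2.0 * np.pi)
VAR_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Gaussian mixture
# ---------------------------------------------------------------------------

@dataclass
class GMMModel:
    weights: np.ndarray            # (K,)
    means: np.ndarray              # (K, D)
    covariances: np.ndarray        # (K, D) diag or (K, D, D) full
    covariance_type: str
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_prob(self, z: np.ndarray) -> np.ndarray | float:
        return gmm_log_prob(self, z)

    def bic(self, Z: np.ndarray) -> float:
        K, D = self.means.shape
        cov_params = K * D if self.covariance_type == "diag" else K * D * (D + 1) / 2
        n_params = (K - 1) + K * D + cov_params
        ll = float(np.sum(gmm_log_prob(self, Z)))
        return n_params * np.log(len(Z)) - 2.0 * ll


def _component_log_dens(means, covs, cov_type, Z) -> np.ndarray:
    """(N, K) matrix of per-component Gaussian log densities."""
    N, D = Z.shape
    K = len(means)
    out = np.empty((N, K))
    if cov_type == "diag":
        for k in range(K):
            diff = Z - means[k]
            out[:, k] = -0.5 * (
                D * _LOG_2PI + np.sum(np.log(covs[k]))
                + np.sum(diff**2 / covs[k], axis=1)
            )
    else:
        for k in range(K):
            L = np.linalg.cholesky(covs[k])
            diff = Z - means[k]
            sol = np.linalg.solve(L, diff.T)
            out[:, k] = -0.5 * (
                D * _LOG_2PI + 2.0 * np.sum(np.log(np.diag(L)))
                + np.sum(sol**2, axis=0)
            )
    return out


def _em_once(Z, K, cov_type, max_iter, tol, rng) -> tuple[GMMModel, float]:
    N, D = Z.shape
    km = KMeans(n_clusters=K, n_init=1,
                random_state=int(rng.integers(2**31))).fit(Z)
    means = km.cluster_centers_.copy()
    weights = np.bincount(km.labels_, minlength=K).astype(float)
    weights = np.maximum(weights, 1.0)
    weights /= weights.sum()
    if cov_type == "diag":
        covs = np.tile(np.maximum(Z.var(axis=0), VAR_FLOOR), (K, 1))
    else:
        base = np.cov(Z.T) + VAR_FLOOR * np.eye(D)
        covs = np.tile(base, (K, 1, 1))

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step
        log_dens = _component_log_dens(means, covs, cov_type, Z)
        weighted = log_dens + np.log(weights)
        norm = logsumexp(weighted, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(weighted - norm[:, None])
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-10)
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / N
        means = (resp.T @ Z) / nk[:, None]
        if cov_type == "diag":
            for k in range(K):
                diff = Z - means[k]
                covs[k] = np.maximum((resp[:, k] @ diff**2) / nk[k], VAR_FLOOR)
        else:
            for k in range(K):
                diff = Z - means[k]
                covs[k] = (resp[:, k] * diff.T) @ diff / nk[k] \
                    + VAR_FLOOR * np.eye(D)
        if ll - prev < tol * max(abs(ll), 1.0) and np.isfinite(prev):
            break
        prev = ll
    model = GMMModel(weights=weights, means=means, covariances=covs,
                     covariance_type=cov_type, log_likelihood_trace=trace)
    return model, trace[-1]


def fit_gmm(Z: np.ndarray, K: int, n_init: int = 3, max_iter: int = 200,
            tol: float = 1e-7, covariance_type: str = "diag",
            seed: int = 0) -> GMMModel:
    """EM fit of a K-component mixture; best of ``n_init`` k-means restarts."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2:
        raise ValueError("Z must be an (N, D) matrix")
    if not np.isfinite(Z).all():
        raise ValueError("non-finite values in Z")
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    N = len(Z)
    if N <= K:
        raise ValueError(f"need more points than components (N={N}, K={K})")
    if np.allclose(Z, Z[0], atol=1e-12):
        raise ValueError("degenerate input: all representations identical")
    if covariance_type not in ("diag", "full"):
        raise ValueError(f"unknown covariance_type {covariance_type!r}")

    rng = np.random.default_rng(seed)
    best: GMMModel | None = None
    best_ll = -np.inf
    for _ in range(max(n_init, 1)):
        model, ll = _em_once(Z, K, covariance_type, max_iter, tol, rng)
        if ll > best_ll:
            best, best_ll = model, ll
    return best


def gmm_log_prob(model: GMMModel, z: np.ndarray) -> np.ndarray | float:
    """log sum_k w_k N(z; mu_k, Sigma_k) via log-sum-exp; scalar for a single z."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    Z = z[None] if single else z
    if Z.shape[1] != model.dim:
        raise ValueError(f"dimension mismatch: model D={model.dim}, z D={Z.shape[1]}")
    log_dens = _component_log_dens(model.means, model.covariances,
                                   model.covariance_type, Z)
    out = logsumexp(log_dens + np.log(model.weights), axis=1)
    return float(out[0]) if single else out


def select_k_bic(Z: np.ndarray, k_max: int = 10, seed: int = 0,
                 **fit_kwargs) -> GMMModel:
    """Fit K in 1..k_max and return the model minimizing BIC."""
    best = None
    best_bic = np.inf
    for k in range(1, min(k_max, len(Z) - 1) + 1):
        model = fit_gmm(Z, k, seed=seed, **fit_kwargs)
        b = model.bic(Z)
        if b < best_bic:
            best, best_bic = model, b
    return best


# ---------------------------------------------------------------------------
# normalizing flow (affine couplings)
# ---------------------------------------------------------------------------

_S_CAP = 3.0  # tanh cap on log-scales keeps couplings well-conditioned


@dataclass
class FlowModel:
    """Affine-coupling flow with alternating binary masks.

    The forward map sends data to a standard-normal base space; log_prob is
    the base log-density of the mapped point plus the accumulated
    log |det J|. An input standardization (fitted mean/scale) is folded into
    the change of variables. Zero-initialized couplings make the untrained
    flow the identity, so its log_prob equals the base density exactly.
    """

    dim: int
    masks: np.ndarray                # (L, D) binary
    s_nets: list[MLP]
    t_nets: list[MLP]
    shift: np.ndarray                # standardization mean, (D,)
    scale: np.ndarray                # standardization sd, (D,)
    loss_trace: list[float] = field(default_factory=list)

    @property
    def params(self):
        return [p for net in (*self.s_nets, *self.t_nets) for p in net.params]

    def _forward_t(self, z: Tensor) -> tuple[Tensor, Tensor]:
        x = (z - Tensor(self.shift)) / Tensor(self.scale)
        logdet_std = -float(np.sum(np.log(self.scale)))
        logdet = Tensor(np.zeros(x.shape[0])) + logdet_std
        for mask, s_net, t_net in zip(self.masks, self.s_nets, self.t_nets):
            m = Tensor(mask)
            xm = x * m
            s = s_net(xm).tanh() * _S_CAP * (1.0 - m)
            t = t_net(xm) * (1.0 - m)
            x = xm + (1.0 - m) * (x * s.exp() + t)
            logdet = logdet + s.sum(axis=1)
        return x, logdet

    def forward(self, z: np.ndarray) -> np.ndarray:
        u, _ = self._forward_t(Tensor(np.atleast_2d(z)))
        return u.data

    def inverse(self, u: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(u, dtype=np.float64)).copy()
        for mask, s_net, t_net in zip(self.masks[::-1], self.s_nets[::-1],
                                      self.t_nets[::-1]):
            xm = x * mask
            s = np.tanh(s_net(Tensor(xm)).data) * _S_CAP * (1.0 - mask)
            t = t_net(Tensor(xm)).data * (1.0 - mask)
            x = xm + (1.0 - mask) * (x - t) * np.exp(-s)
        return x * self.scale + self.shift

    def log_prob(self, z: np.ndarray) -> np.ndarray | float:
        return flow_log_prob(self, z)


def init_flow(dim: int, n_layers: int = 6, hidden_units: int = 64,
              seed: int = 0) -> FlowModel:
    """Identity-initialized flow (couplings output zero scale and shift)."""
    if dim < 2:
        raise ValueError(
            "normalizing flow needs dim >= 2 (couplings split dimensions); "
            "pad 1-D representations or use the GMM family instead"
        )
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_layers, dim))
    for layer in range(n_layers):
        masks[layer, layer % 2::2] = 1.0  # alternating even/odd coordinates
    s_nets = [MLP([dim, hidden_units, dim], rng, activation="tanh",
                  zero_last=True) for _ in range(n_layers)]
    t_nets = [MLP([dim, hidden_units, dim], rng, activation="tanh",
                  zero_last=True) for _ in range(n_layers)]
    return FlowModel(dim=dim, masks=masks, s_nets=s_nets, t_nets=t_nets,
                     shift=np.zeros(dim), scale=np.ones(dim))


def fit_flow(Z: np.ndarray, n_layers: int = 6, hidden_units: int = 64,
             epochs: int = 200, lr: float = 1e-3, seed: int = 0) -> FlowModel:
    """Maximize mean log-likelihood of Z by full-batch gradient ascent."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or not np.isfinite(Z).all():
        raise ValueError("Z must be a finite (N, D) matrix")
    flow = init_flow(Z.shape[1], n_layers, hidden_units, seed)
    flow.shift = Z.mean(axis=0)
    flow.scale = np.maximum(Z.std(axis=0), 1e-6)
    opt = Adam(flow.params, lr=lr)
    D = Z.shape[1]
    for _ in range(epochs):
        u, logdet = flow._forward_t(Tensor(Z))
        base_lp = (u * u).sum(axis=1) * -0.5 - 0.5 * D * _LOG_2PI
        nll = -(base_lp + logdet).mean()
        if not np.isfinite(nll.data):
            raise RuntimeError(f"NaN/inf flow loss at epoch {len(flow.loss_trace)}")
        opt.zero_grad()
        nll.backward()
        opt.step()
        flow.loss_trace.append(float(nll.data))
    return flow


def flow_log_prob(model: FlowModel, z: np.ndarray) -> np.ndarray | float:
    """Change-of-variables density: base log N(u; 0, I) + log |det J|."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    Z = z[None] if single else z
    if Z.shape[1] != model.dim:
        raise ValueError(f"dimension mismatch: flow D={model.dim}, z D={Z.shape[1]}")
    u, logdet = model._forward_t(Tensor(Z))
    lp = -0.5 * np.sum(u.data**2, axis=1) - 0.5 * model.dim * _LOG_2PI \
        + logdet.data
    return float(lp[0]) if single else lp


# ---------------------------------------------------------------------------
# anomaly scoring
# ---------------------------------------------------------------------------

def anomaly_score(model, rep: Representation) -> AnomalyScore:
    """s = -log p(z): higher score, lower likelihood, more anomalous."""
    return AnomalyScore(s=-float(model.log_prob(rep.z)),
                        subject_id=rep.subject_id, origin=rep.origin)


def score_representations(model, reps: list[Representation]) -> list[AnomalyScore]:
    if not reps:
        return []
    Z = np.stack([r.z for r in reps])
    s = -np.atleast_1d(model.log_prob(Z))
    return [AnomalyScore(s=float(si), subject_id=r.subject_id, origin=r.origin)
            for si, r in zip(s, reps)]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_density(model, path) -> None:
    if isinstance(model, GMMModel):
        np.savez(path, __family__="gmm",
                 __meta__=json.dumps({"covariance_type": model.covariance_type}),
                 weights=model.weights, means=model.means,
                 covariances=model.covariances,
                 trace=np.asarray(model.log_likelihood_trace))
    elif isinstance(model, FlowModel):
        arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
        meta = {"dim": model.dim, "n_layers": len(model.s_nets),
                "hidden_units": model.s_nets[0].layers[0].W.shape[1]}
        np.savez(path, __family__="flow", __meta__=json.dumps(meta),
                 masks=model.masks, shift=model.shift, scale=model.scale,
                 trace=np.asarray(model.loss_trace), **arrays)
    else:
        raise TypeError(f"unknown density model {type(model).__name__}")


def load_density(path):
    with np.load(path, allow_pickle=False) as f:
        family = str(f["__family__"])
        meta = json.loads(str(f["__meta__"]))
        if family == "gmm":
            return GMMModel(weights=f["weights"], means=f["means"],
                            covariances=f["covariances"],
                            covariance_type=meta["covariance_type"],
                            log_likelihood_trace=f["trace"].tolist())
        flow = init_flow(meta["dim"], meta["n_layers"], meta["hidden_units"])
        flow.masks = f["masks"]
        flow.shift = f["shift"]
        flow.scale = f["scale"]
        flow.loss_trace = f["trace"].tolist()
        for i, p in enumerate(flow.params):
            p.data = f[f"p{i}"].astype(np.float64)
        return flow
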