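"""Restricted Boltzmann Machine over aligned categorical sequences.

Visible layer: ``n_sites`` categorical units over ``q`` states (20 residues
plus gap). Hidden layer: ``n_hidden`` real-valued units with a double
rectified linear (dReLU) potential

    U(h) = 1/2 gamma_+ h_+^2 + 1/2 gamma_- h_-^2 + theta_+ h_+ + theta_- h_-

whose cumulant function Gamma(I) = log int dh exp(-U(h) + h I) has a closed
form in terms of the scaled complementary error function; both half-line
integrals are evaluated in the log domain so scores remain finite for |I| up
to at least 1e3.

The marginal log-probability of a sequence is

    log P(v) = sum_i g_i(v_i) + sum_mu Gamma_mu(I_mu(v)) - log Z,
    I_mu(v)  = sum_i w_{i,mu}(v_i).

Training maximizes the weighted data log-likelihood, penalized by an
L1-squared weight regularizer ( lambda1^2 / (2 q N) * sum_mu (sum |w|)^2 ),
with persistent contrastive divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erfcx, logsumexp

from .alphabet import N_STATES
from .encoding import decode_indices

_LOG2 = np.log(2.0)
_HALF_LOG_PI_OVER_2 = 0.5 * np.log(np.pi / 2.0)


def log_erfcx(x: np.ndarray) -> np.ndarray:
    """log(erfcx(x)), stable for large negative x where erfcx overflows."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < -5.0
    xs = x[~small]
    out[~small] = np.log(erfcx(xs))
    xl = x[small]
    # erfcx(x) = 2 exp(x^2) - erfcx(-x)
    out[small] = xl * xl + _LOG2 + np.log1p(-np.exp(-xl * xl) * erfcx(-xl) / 2.0)
    return out


@dataclass
class DReLUParams:
    """Per-hidden-unit dReLU potential parameters (arrays of shape (n_hidden,))."""

    gamma_plus: np.ndarray
    gamma_minus: np.ndarray
    theta_plus: np.ndarray
    theta_minus: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.gamma_plus, self.gamma_minus):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("dReLU curvatures must be positive")

    @classmethod
    def standard(cls, n_hidden: int) -> "DReLUParams":
        return cls(
            np.ones(n_hidden), np.ones(n_hidden), np.zeros(n_hidden), np.zeros(n_hidden)
        )

    def copy(self) -> "DReLUParams":
        return DReLUParams(
            self.gamma_plus.copy(),
            self.gamma_minus.copy(),
            self.theta_plus.copy(),
            self.theta_minus.copy(),
        )


def _half_log_integrals(params: DReLUParams, I: np.ndarray):
    """Log of the two half-line integrals of exp(-U(h) + h I).

    Returns (log_plus, log_minus), each broadcast over I's shape.
    """
    gp, gm = params.gamma_plus, params.gamma_minus
    tp, tm = params.theta_plus, params.theta_minus
    ap = I - tp
    am = tm - I  # sign-flipped argument of the negative half-line
    log_plus = _HALF_LOG_PI_OVER_2 - 0.5 * np.log(gp) + log_erfcx(-ap / np.sqrt(2 * gp))
    log_minus = _HALF_LOG_PI_OVER_2 - 0.5 * np.log(gm) + log_erfcx(-am / np.sqrt(2 * gm))
    return log_plus, log_minus


def gamma_dreu(params: DReLUParams, I: np.ndarray) -> np.ndarray:
    """Cumulant Gamma(I) = log int dh exp(-U(h) + h I), elementwise."""
    log_plus, log_minus = _half_log_integrals(params, np.asarray(I, dtype=float))
    return np.logaddexp(log_plus, log_minus)


def _truncnorm_stats(a: np.ndarray, gamma: np.ndarray):
    """Moments of N(a/gamma, 1/gamma) truncated to [0, inf).

    Returns (E[h], E[h^2]) using the inverse-Mills ratio evaluated through
    erfcx for tail stability.
    """
    s2 = 1.0 / gamma
    s = np.sqrt(s2)
    mu = a * s2
    alpha = -mu / s
    lam = np.sqrt(2.0 / np.pi) * np.exp(-log_erfcx(alpha / np.sqrt(2.0)))
    e1 = mu + s * lam
    e2 = s2 + mu * mu + mu * s * lam
    return e1, e2


def dreu_moments(params: DReLUParams, I: np.ndarray) -> dict[str, np.ndarray]:
    """Conditional moments of h given input I under the dReLU potential.

    Keys: ``p_plus`` (weight of the positive branch), ``h`` = E[h|I],
    ``h_plus``, ``h_minus``, ``h_plus_sq``, ``h_minus_sq`` (moments of the
    rectified halves), plus the branch means/variances used for sampling.
    """
    I = np.asarray(I, dtype=float)
    gp, gm = params.gamma_plus, params.gamma_minus
    tp, tm = params.theta_plus, params.theta_minus
    log_plus, log_minus = _half_log_integrals(params, I)
    log_norm = np.logaddexp(log_plus, log_minus)
    p_plus = np.exp(log_plus - log_norm)
    p_minus = 1.0 - p_plus
    e1p, e2p = _truncnorm_stats(I - tp, gp)
    e1m, e2m = _truncnorm_stats(tm - I, gm)  # moments of u = -h on the minus side
    return {
        "p_plus": p_plus,
        "h": p_plus * e1p - p_minus * e1m,
        "h_plus": p_plus * e1p,
        "h_minus": -p_minus * e1m,
        "h_plus_sq": p_plus * e2p,
        "h_minus_sq": p_minus * e2m,
    }


@dataclass
class RBMModel:
    g: np.ndarray  # (n_sites, q) local potentials
    W: np.ndarray  # (n_sites, n_hidden, q) weights
    hidden: DReLUParams
    n_sites: int
    n_states: int = N_STATES
    log_z: float | None = None
    log_z_method: str | None = None
    log_z_stderr: float | None = None

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @classmethod
    def zeros(cls, n_sites: int, n_hidden: int, n_states: int = N_STATES) -> "RBMModel":
        return cls(
            g=np.zeros((n_sites, n_states)),
            W=np.zeros((n_sites, n_hidden, n_states)),
            hidden=DReLUParams.standard(n_hidden),
            n_sites=n_sites,
            n_states=n_states,
        )

    def copy(self) -> "RBMModel":
        return RBMModel(
            self.g.copy(), self.W.copy(), self.hidden.copy(), self.n_sites,
            self.n_states, self.log_z, self.log_z_method, self.log_z_stderr,
        )


def _as_index_matrix(seqs: np.ndarray) -> np.ndarray:
    V = np.asarray(seqs)
    if V.ndim == 1:
        V = V[None, :]
    return V


def hidden_input(model: RBMModel, seqs: np.ndarray) -> np.ndarray:
    """I_mu(v) = sum_i w_{i,mu}(v_i) for each row of integer-encoded seqs."""
    V = _as_index_matrix(seqs)
    if V.shape[1] != model.n_sites:
        raise ValueError(f"sequence width {V.shape[1]} != model sites {model.n_sites}")
    sites = np.arange(model.n_sites)
    # (B, n_sites, n_hidden) gather then sum over sites
    return model.W[sites[None, :], :, V].sum(axis=1)


def log_score(model: RBMModel, seqs: np.ndarray) -> np.ndarray:
    """Unnormalized log-probability sum_i g_i(v_i) + sum_mu Gamma_mu(I_mu)."""
    V = _as_index_matrix(seqs)
    sites = np.arange(model.n_sites)
    g_term = model.g[sites[None, :], V].sum(axis=1)
    I = hidden_input(model, V)
    gamma_term = gamma_dreu(model.hidden, I).sum(axis=1)
    return g_term + gamma_term


def log_likelihood(model: RBMModel, seqs: np.ndarray) -> np.ndarray:
    if model.log_z is None:
        raise ValueError("log_z not set; call log_partition first")
    return log_score(model, seqs) - model.log_z


def project(model: RBMModel, seqs: np.ndarray) -> np.ndarray:
    """Latent representation: rows of hidden inputs (one per sequence)."""
    return hidden_input(model, seqs)


def _enumerate_space(n_sites: int, n_states: int) -> np.ndarray:
    if n_states ** n_sites > 10 ** 7:
        raise ValueError("state space too large for exact enumeration")
    grids = np.meshgrid(*([np.arange(n_states)] * n_sites), indexing="ij")
    return np.stack([grid.ravel() for grid in grids], axis=1)


def log_partition_exact(model: RBMModel) -> float:
    space = _enumerate_space(model.n_sites, model.n_states)
    return float(logsumexp(log_score(model, space)))


def _sample_hidden(model: RBMModel, I: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample h | I: a two-sided truncated-Gaussian mixture."""
    p = model.hidden
    mom = dreu_moments(p, I)
    side_plus = rng.random(I.shape) < mom["p_plus"]
    out = np.empty_like(I)
    for sign, gamma, theta, mask in (
        (1.0, p.gamma_plus, p.theta_plus, side_plus),
        (-1.0, p.gamma_minus, p.theta_minus, ~side_plus),
    ):
        if not mask.any():
            continue
        th = np.broadcast_to(theta, I.shape)[mask]
        ga = np.broadcast_to(gamma, I.shape)[mask]
        a = sign * (I[mask] - th)  # natural parameter of the half-Gaussian in u = sign*h
        mu = a / ga
        s = 1.0 / np.sqrt(ga)
        u = _sample_lower_truncnorm(mu, s, rng)
        out[mask] = sign * u
    return out


def _sample_lower_truncnorm(mu: np.ndarray, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample N(mu, s^2) truncated to [0, inf), vectorized and tail-robust."""
    alpha = -mu / s
    out = np.empty_like(mu)
    easy = alpha < 3.0  # acceptance of naive rejection is fine
    if easy.any():
        m, sd, n = mu[easy], s[easy], int(easy.sum())
        res = np.full(n, np.nan)
        todo = np.ones(n, dtype=bool)
        for _ in range(100):
            draw = m[todo] + sd[todo] * rng.standard_normal(todo.sum())
            ok = draw >= 0
            idx = np.flatnonzero(todo)[ok]
            res[idx] = draw[ok]
            todo[idx] = False
            if not todo.any():
                break
        if todo.any():  # extremely unlikely stragglers: exponential proposal
            res[todo] = _tail_truncnorm(mu[easy][todo], s[easy][todo], rng)
        out[easy] = res
    hard = ~easy
    if hard.any():
        out[hard] = _tail_truncnorm(mu[hard], s[hard], rng)
    return out


def _tail_truncnorm(mu: np.ndarray, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Robert's exponential rejection sampler for far-tail truncated normals."""
    alpha_std = -mu / s
    n = alpha_std.shape[0]
    res = np.full(n, np.nan)
    todo = np.ones(n, dtype=bool)
    lam = (alpha_std + np.sqrt(alpha_std ** 2 + 4.0)) / 2.0
    for _ in range(200):
        k = int(todo.sum())
        z = alpha_std[todo] + rng.exponential(1.0, k) / lam[todo]
        rho = np.exp(-0.5 * (z - lam[todo]) ** 2)
        ok = rng.random(k) <= rho
        idx = np.flatnonzero(todo)[ok]
        res[idx] = mu[idx] + s[idx] * z[ok]
        todo[idx] = False
        if not todo.any():
            break
    if todo.any():
        res[todo] = np.maximum(mu[todo], 0.0)  # deterministic fallback
    return res


def _sample_visible(model: RBMModel, h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample v | h: independent categoricals with fields g + sum_mu h_mu w."""
    B = h.shape[0]
    N, M, q = model.W.shape
    fields = model.g[None, :, :] + (h @ model.W.transpose(1, 0, 2).reshape(M, N * q)).reshape(B, N, q)
    gumbel = rng.gumbel(size=fields.shape)
    return (fields + gumbel).argmax(axis=2)


def gibbs_step(model: RBMModel, V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    I = hidden_input(model, V)
    h = _sample_hidden(model, I, rng)
    return _sample_visible(model, h, rng)


def sample(
    model: RBMModel,
    n: int,
    gibbs_steps: int = 100,
    seed: int | np.random.Generator = 0,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Draw n sequences by Gibbs sampling (integer-encoded rows)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = init if init is not None else rng.integers(0, model.n_states, size=(n, model.n_sites))
    for _ in range(gibbs_steps):
        V = gibbs_step(model, V, rng)
    return V


def sample_sequences(model: RBMModel, n: int, gibbs_steps: int = 100, seed=0) -> list[str]:
    return [decode_indices(v) for v in sample(model, n, gibbs_steps, seed)]


def _log_z_independent(model: RBMModel) -> float:
    """Closed-form log Z of the W=0 model with the same g and hidden params."""
    return float(
        logsumexp(model.g, axis=1).sum()
        + gamma_dreu(model.hidden, np.zeros(model.n_hidden)).sum()
    )


def log_partition_ais(
    model: RBMModel,
    n_chains: int = 20,
    n_betas: int = 1000,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> tuple[float, float]:
    """Annealed importance sampling from the independent-site (W=0) base model.

    Returns (log_z_estimate, bootstrap standard error).
    """
    rng = np.random.default_rng(seed)
    base = model.copy()
    base.W = np.zeros_like(model.W)
    log_z0 = _log_z_independent(model)

    # exact sample from the factorized base model
    probs = np.exp(model.g - logsumexp(model.g, axis=1, keepdims=True))
    V = np.stack(
        [rng.choice(model.n_states, size=n_chains, p=probs[i]) for i in range(model.n_sites)],
        axis=1,
    )
    betas = np.linspace(0.0, 1.0, n_betas + 1)
    log_w = np.zeros(n_chains)
    annealed = model.copy()
    for b_prev, b_next in zip(betas[:-1], betas[1:]):
        I = hidden_input(model, V)
        log_w += (gamma_dreu(model.hidden, b_next * I)
                  - gamma_dreu(model.hidden, b_prev * I)).sum(axis=1)
        annealed.W = b_next * model.W
        V = gibbs_step(annealed, V, rng)
    log_z = log_z0 + logsumexp(log_w) - np.log(n_chains)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_chains, n_chains)
        boot[b] = log_z0 + logsumexp(log_w[idx]) - np.log(n_chains)
    return float(log_z), float(boot.std(ddof=1))


def log_partition(model: RBMModel, method: str = "exact_enum", **settings) -> tuple[float, float]:
    """Estimate log Z and cache it on the model. Returns (estimate, stderr)."""
    if method == "exact_enum":
        lz, err = log_partition_exact(model), 0.0
    elif method == "ais":
        lz, err = log_partition_ais(model, **settings)
    else:
        raise ValueError(f"unknown method {method!r}")
    model.log_z, model.log_z_method, model.log_z_stderr = lz, method, err
    return lz, err


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _one_hot_means(V: np.ndarray, weights: np.ndarray, n_sites: int, n_states: int) -> np.ndarray:
    w = weights / weights.sum()
    out = np.zeros((n_sites, n_states))
    for i in range(n_sites):
        np.add.at(out[i], V[:, i], w)
    return out


def _weight_stats(V: np.ndarray, H: np.ndarray, weights: np.ndarray, n_sites: int, n_states: int) -> np.ndarray:
    """< 1[v_i = a] * H_mu > weighted over rows -> (n_sites, n_hidden, n_states)."""
    w = weights / weights.sum()
    M = H.shape[1]
    out = np.zeros((n_sites, M, n_states))
    wh = H * w[:, None]
    for i in range(n_sites):
        acc = np.zeros((n_states, M))
        np.add.at(acc, V[:, i], wh)
        out[i] = acc.T
    return out


def _moment_gradients(model: RBMModel, V: np.ndarray, weights: np.ndarray):
    """Expectations of all sufficient statistics under rows V with weights."""
    I = hidden_input(model, V)
    mom = dreu_moments(model.hidden, I)
    H = mom["h"]
    w = weights / weights.sum()
    stats = {
        "g": _one_hot_means(V, weights, model.n_sites, model.n_states),
        "W": _weight_stats(V, H, weights, model.n_sites, model.n_states),
        # d log P / d theta_+ = -E[h_+]; d log P / d gamma_+ = -E[h_+^2]/2
        "theta_plus": -(w[:, None] * mom["h_plus"]).sum(axis=0),
        "theta_minus": -(w[:, None] * mom["h_minus"]).sum(axis=0),
        "gamma_plus": -0.5 * (w[:, None] * mom["h_plus_sq"]).sum(axis=0),
        "gamma_minus": -0.5 * (w[:, None] * mom["h_minus_sq"]).sum(axis=0),
    }
    return stats


def regularization_penalty(model: RBMModel, l1sq: float) -> float:
    """lambda1^2 / (2 q N) * sum_mu ( sum_{i,a} |w_{i,mu}(a)| )^2"""
    per_hidden = np.abs(model.W).sum(axis=(0, 2))
    return l1sq / (2.0 * model.n_states * model.n_sites) * float((per_hidden ** 2).sum())


def _regularization_grad(model: RBMModel, l1sq: float) -> np.ndarray:
    per_hidden = np.abs(model.W).sum(axis=(0, 2))  # (n_hidden,)
    return (l1sq / (model.n_states * model.n_sites)) * per_hidden[None, :, None] * np.sign(model.W)


def objective_exact(model: RBMModel, V: np.ndarray, weights: np.ndarray, l1sq: float) -> float:
    """Regularized weighted log-likelihood with exact log Z (tiny models only)."""
    w = weights / weights.sum()
    ll = float((w * log_score(model, V)).sum()) - log_partition_exact(model)
    return ll - regularization_penalty(model, l1sq)


def gradient_exact(model: RBMModel, V: np.ndarray, weights: np.ndarray, l1sq: float) -> dict[str, np.ndarray]:
    """Exact gradient of objective_exact (model term by full enumeration)."""
    space = _enumerate_space(model.n_sites, model.n_states)
    ls = log_score(model, space)
    p = np.exp(ls - logsumexp(ls))
    data = _moment_gradients(model, V, weights)
    mod = _moment_gradients(model, space, p)
    grad = {k: data[k] - mod[k] for k in data}
    grad["W"] -= _regularization_grad(model, l1sq)
    return grad


@dataclass
class TrainingLog:
    epochs: list[int] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    weight_norm: list[float] = field(default_factory=list)


def train_rbm(
    sequences: np.ndarray,
    weights: np.ndarray | None = None,
    n_hidden: int = 25,
    l1sq: float = 0.1,
    epochs: int = 200,
    batch_size: int = 128,
    learning_rate: float = 2e-2,
    n_chains: int = 100,
    gibbs_steps: int = 10,
    seed: int = 0,
    n_states: int = N_STATES,
) -> tuple[RBMModel, TrainingLog]:
    """Fit an RBM to integer-encoded aligned sequences by weighted PCD.

    ``sequences`` is an (n, n_sites) integer matrix; ``weights`` the clone
    multiplicities (default all ones). The learning rate halves at each third
    of training. Deterministic given ``seed``.
    """
    V = np.asarray(sequences, dtype=np.int64)
    if V.ndim != 2 or V.size == 0:
        raise ValueError("sequences must be a non-empty (n, n_sites) matrix")
    n, n_sites = V.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    for name, val in (("n_hidden", n_hidden), ("epochs", epochs),
                      ("batch_size", batch_size), ("learning_rate", learning_rate),
                      ("n_chains", n_chains), ("gibbs_steps", gibbs_steps)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    if l1sq < 0:
        raise ValueError("l1sq must be non-negative")

    rng = np.random.default_rng(seed)
    model = RBMModel.zeros(n_sites, n_hidden, n_states)
    freqs = _one_hot_means(V, weights, n_sites, n_states)
    model.g = np.log(freqs + 1e-6)
    model.g -= model.g.mean(axis=1, keepdims=True)
    model.W = 0.01 * rng.standard_normal(model.W.shape)

    log_gp = np.zeros(n_hidden)
    log_gm = np.zeros(n_hidden)

    chains = V[rng.choice(n, size=n_chains, p=weights / weights.sum())].copy()
    p_batch = weights / weights.sum()
    batches_per_epoch = max(1, n // batch_size)
    log = TrainingLog()

    for epoch in range(epochs):
        lr = learning_rate * (0.5 ** (3 * epoch // max(1, epochs)))
        for _ in range(batches_per_epoch):
            idx = rng.choice(n, size=min(batch_size, n), p=p_batch)
            Vb = V[idx]
            wb = np.ones(len(idx))
            for _ in range(gibbs_steps):
                chains = gibbs_step(model, chains, rng)
            data = _moment_gradients(model, Vb, wb)
            mod = _moment_gradients(model, chains, np.ones(n_chains))
            g_grad = data["g"] - mod["g"]
            W_grad = data["W"] - mod["W"] - _regularization_grad(model, l1sq)
            model.g += lr * g_grad
            model.W += lr * W_grad
            h = model.hidden
            log_gp += lr * h.gamma_plus * (data["gamma_plus"] - mod["gamma_plus"])
            log_gm += lr * h.gamma_minus * (data["gamma_minus"] - mod["gamma_minus"])
            tp_grad = data["theta_plus"] - mod["theta_plus"]
            tm_grad = data["theta_minus"] - mod["theta_minus"]
            log_gp = np.clip(log_gp, -4.0, 4.0)
            log_gm = np.clip(log_gm, -4.0, 4.0)
            model.hidden = DReLUParams(
                np.exp(log_gp),
                np.exp(log_gm),
                h.theta_plus + lr * tp_grad,
                h.theta_minus + lr * tm_grad,
            )
            if not np.isfinite(model.W).all() or not np.isfinite(model.g).all():
                raise FloatingPointError(
                    f"NaN/inf in parameters at epoch {epoch}; reduce learning rate"
                )
        # cheap likelihood proxy: mean unnormalized score gap data vs chains
        proxy = float(log_score(model, V[: min(n, 500)]).mean() - log_score(model, chains).mean())
        log.epochs.append(epoch)
        log.objective.append(proxy)
        log.weight_norm.append(float(np.abs(model.W).sum(axis=(0, 2)).mean()))
    return model, log


def fit_independent_site(
    sequences: np.ndarray,
    weights: np.ndarray | None = None,
    pseudocount: float = 1e-6,
    n_states: int = N_STATES,
) -> RBMModel:
    """Closed-form independent-site (PWM) model: an RBM with no hidden units.

    g is the log of the weighted single-site frequencies and log Z is exact,
    so log_likelihood is the PWM log-probability.
    """
    V = np.asarray(sequences, dtype=np.int64)
    if V.ndim != 2 or V.size == 0:
        raise ValueError("sequences must be a non-empty (n, n_sites) matrix")
    if weights is None:
        weights = np.ones(V.shape[0])
    freqs = _one_hot_means(V, np.asarray(weights, dtype=float), V.shape[1], n_states)
    freqs = freqs + pseudocount
    freqs /= freqs.sum(axis=1, keepdims=True)
    model = RBMModel.zeros(V.shape[1], 0, n_states)
    model.g = np.log(freqs)
    model.log_z, model.log_z_method, model.log_z_stderr = (
        _log_z_independent(model), "closed_form", 0.0,
    )
    return model


# ---------------------------------------------------------------------------
# persistence & exports
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def export_parameters(model: RBMModel, path: str | Path) -> None:
    """Save all parameters plus metadata to a single .npz archive."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "n_sites": model.n_sites,
        "n_states": model.n_states,
        "n_hidden": model.n_hidden,
        "log_z": model.log_z,
        "log_z_method": model.log_z_method,
        "log_z_stderr": model.log_z_stderr,
    }
    np.savez(
        path,
        g=model.g,
        W=model.W,
        gamma_plus=model.hidden.gamma_plus,
        gamma_minus=model.hidden.gamma_minus,
        theta_plus=model.hidden.theta_plus,
        theta_minus=model.hidden.theta_minus,
        meta=np.array(json.dumps(meta)),
    )


def import_parameters(path: str | Path) -> RBMModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta['format_version']}")
        model = RBMModel(
            g=data["g"],
            W=data["W"],
            hidden=DReLUParams(
                data["gamma_plus"], data["gamma_minus"],
                data["theta_plus"], data["theta_minus"],
            ),
            n_sites=meta["n_sites"],
            n_states=meta["n_states"],
            log_z=meta["log_z"],
            log_z_method=meta["log_z_method"],
            log_z_stderr=meta["log_z_stderr"],
        )
    return model


def export_field_pwm(model: RBMModel) -> np.ndarray:
    """Normalized exp(g): a PWM-style view of the local potentials."""
    p = np.exp(model.g)
    return p / p.sum(axis=1, keepdims=True)
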