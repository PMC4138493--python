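"""Gaussian-visible restricted Boltzmann machine with tanh or logistic
hidden units, trained by CD-1 with L1 weight decay.

The visible layer models voxels as real-valued Gaussian units; the hidden
layer is binary, either logistic ({0, 1}) or hyperbolic-tangent ({-1, +1}).
The tanh choice makes the model symmetric under a joint sign flip of a
receptive field and its hidden unit, which avoids learning duplicate
features of opposite sign when source activity crosses baseline.

Two energy conventions are supported.  The *printed* form writes the
visible containment term as (a - v)^2 / sigma^2 (no 1/2 factor), which
implies conditional visible variance sigma^2/2 and mean a + (sigma/2) W^T h.
The *standard* Gaussian-RBM form carries the conventional 1/2, giving
variance sigma^2 and mean a + sigma W^T h, and is the default everywhere:
with voxels z-scored and sigma fixed at 1 the two differ only by this
bookkeeping, and the standard form is the one the practical literature
trains.  ``sigma`` is fixed, not learned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy.special import expit, logsumexp

HIDDEN_TYPES = ("tanh", "logistic")
VISIBLE_TYPES = ("gaussian", "logistic")


@dataclass(frozen=True)
class RBMParams:
    """Parameters of one RBM.  Rows of ``W`` are the receptive fields
    ("features"): one weight per visible unit (voxel)."""

    W: np.ndarray                 # (n_hidden, n_visible)
    a: np.ndarray                 # visible biases (n_visible,)
    b: np.ndarray                 # hidden biases (n_hidden,)
    sigma: np.ndarray             # visible scales (n_visible,), positive
    hidden_type: str = "tanh"
    visible_type: str = "gaussian"
    standard_form: bool = True

    def __post_init__(self) -> None:
        if self.hidden_type not in HIDDEN_TYPES:
            raise ValueError(f"hidden_type must be one of {HIDDEN_TYPES}")
        if self.visible_type not in VISIBLE_TYPES:
            raise ValueError(f"visible_type must be one of {VISIBLE_TYPES}")
        for arr in (self.W, self.a, self.b, self.sigma):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        H, V = self.W.shape
        if self.a.shape != (V,) or self.b.shape != (H,) or self.sigma.shape != (V,):
            raise ValueError("parameter shapes are inconsistent")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]


def init_params(
    n_visible: int,
    n_hidden: int,
    seed: int = 0,
    hidden_type: str = "tanh",
    visible_type: str = "gaussian",
    init_sd: float = 0.01,
    standard_form: bool = True,
) -> RBMParams:
    """Small-Gaussian weight initialization, zero biases, unit sigma."""
    rng = np.random.default_rng(seed)
    return RBMParams(
        W=rng.normal(0.0, init_sd, size=(n_hidden, n_visible)),
        a=np.zeros(n_visible),
        b=np.zeros(n_hidden),
        sigma=np.ones(n_visible),
        hidden_type=hidden_type,
        visible_type=visible_type,
        standard_form=standard_form,
    )


@dataclass(frozen=True)
class TrainConfig:
    epsilon: float = 0.08
    lambda_l1: float = 0.1
    batch_size: int = 5
    n_epochs: int = 75
    cd_steps: int = 1
    seed: int = 0
    dropout_visible: float = 0.0
    dropout_hidden: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for p in (self.dropout_visible, self.dropout_hidden):
            if not (0.0 <= p < 1.0):
                raise ValueError("dropout probabilities must be in [0, 1)")


@dataclass
class TrainLog:
    """Per-epoch diagnostics of one training run."""

    recon_error: list = field(default_factory=list)   # mean squared error
    mean_abs_w: list = field(default_factory=list)
    n_updates: int = 0


@dataclass(frozen=True)
class Gradients:
    dW: np.ndarray
    da: np.ndarray
    db: np.ndarray


# ---------------------------------------------------------------------------
# energy and conditionals


def energy(v: np.ndarray, h: np.ndarray, p: RBMParams, form: str = "legacy") -> float:
    """Energy of a joint (visible, hidden) configuration.

    ``form="legacy"`` evaluates, verbatim, the formulation some of the
    neuroimaging RBM literature writes:
    ``-sum_ij (v_j/sigma_j) W_ji h_i - sum_j (a_j-v_j)^2/sigma_j^2
    - sum_i b_i h_i`` (all three terms subtracted, no 1/2 on the
    containment).  As written this expression is not normalizable in v; its
    normalizable reading gives the conditionals with variance sigma^2/2 used
    when ``standard_form`` is False.  ``form="standard"`` is the textbook
    Gaussian-RBM energy with +((v-a)^2)/(2 sigma^2) containment, the one the
    exact enumeration oracle integrates.
    """
    v = np.asarray(v, float)
    h = np.asarray(h, float)
    if v.shape != (p.n_visible,) or h.shape != (p.n_hidden,):
        raise ValueError("dimension mismatch")
    interaction = -np.sum((v / p.sigma) * (p.W.T @ h))
    contain = np.sum((p.a - v) ** 2 / p.sigma**2)
    if form == "standard":
        contain = contain / 2.0
    elif form == "legacy":
        contain = -contain
    else:
        raise ValueError("form must be 'legacy' or 'standard'")
    return float(interaction + contain - np.sum(p.b * h))


def hidden_preactivation(v: np.ndarray, p: RBMParams) -> np.ndarray:
    """z = W (v / sigma) + b, for a single vector or a batch (rows)."""
    v = np.atleast_2d(np.asarray(v, float))
    return v / p.sigma @ p.W.T + p.b


def hidden_conditional(
    v: np.ndarray, p: RBMParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Means and (optionally) samples of the hidden units given visibles.

    tanh units: mean tanh(z), samples in {-1, +1} with P(+1) = (1+tanh z)/2.
    logistic units: mean sigmoid(z), samples in {0, 1}.
    """
    v = np.asarray(v, float)
    single = v.ndim == 1
    z = hidden_preactivation(v, p)
    if p.hidden_type == "tanh":
        means = np.tanh(z)
        if rng is not None:
            sample = np.where(rng.random(z.shape) < (1.0 + means) / 2.0, 1.0, -1.0)
    else:
        means = expit(z)
        if rng is not None:
            sample = (rng.random(z.shape) < means).astype(float)
    if rng is None:
        sample = None
    elif single:
        sample = sample[0]
    return (means[0], sample) if single else (means, sample)


def visible_mean(h: np.ndarray, p: RBMParams) -> np.ndarray:
    """Conditional mean of the visibles given hidden states (vector or batch)."""
    h = np.atleast_2d(np.asarray(h, float))
    drive = h @ p.W
    if p.visible_type == "logistic":
        out = expit(drive + p.a)
    elif p.standard_form:
        out = p.a + p.sigma * drive
    else:
        out = p.a + (p.sigma / 2.0) * drive
    return out


def visible_conditional(
    h: np.ndarray, p: RBMParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Means and (optionally) samples of the visibles given hiddens.

    Gaussian visibles: N(a + sigma W^T h, sigma^2) in the standard form, or
    N(a + (sigma/2) W^T h, sigma^2/2) under the printed energy.
    """
    h = np.asarray(h, float)
    single = h.ndim == 1
    means = visible_mean(h, p)
    if rng is None:
        sample = None
    elif p.visible_type == "logistic":
        sample = (rng.random(means.shape) < means).astype(float)
    else:
        sd = p.sigma if p.standard_form else p.sigma / np.sqrt(2.0)
        sample = rng.normal(means, sd)
    if sample is not None and single:
        sample = sample[0]
    return (means[0], sample) if single else (means, sample)


# ---------------------------------------------------------------------------
# gradients and training


def _stats(v: np.ndarray, hm: np.ndarray, p: RBMParams) -> Gradients:
    n = v.shape[0]
    dW = hm.T @ (v / p.sigma) / n
    if p.visible_type == "logistic":
        da = v.mean(axis=0)
    else:
        da = ((v - p.a) / p.sigma**2).mean(axis=0)
    return Gradients(dW=dW, da=da, db=hm.mean(axis=0))


def cd_gradient(
    batch: np.ndarray,
    p: RBMParams,
    cd_steps: int = 1,
    rng: np.random.Generator | None = None,
    hidden_mask: np.ndarray | None = None,
    sample_visible: bool | None = None,
    mean_field: bool = False,
) -> Gradients:
    """Contrastive-divergence estimate of the log-likelihood gradient.

    Positive statistics use hidden means at the data.  The negative phase
    runs ``cd_steps`` alternating Gibbs half-steps with sampled hidden
    states, then takes hidden means at the final reconstruction for the
    statistics.  For CD-1 the visible half-step uses the conditional *mean*
    (the low-variance convention standard in practical training); longer
    chains sample the visibles at every step, so the chain genuinely mixes
    toward the model distribution and the statistics (hidden means at a
    *sampled* final visible state) are asymptotically unbiased.
    ``sample_visible`` overrides this default.  ``mean_field=True`` replaces
    every stochastic half-step by its conditional mean (fully deterministic
    CD, exactly invariant to batch row order).
    """
    batch = np.atleast_2d(np.asarray(batch, float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    if rng is None:
        rng = np.random.default_rng(0)
    if sample_visible is None:
        sample_visible = cd_steps > 1
    pos_hm, _ = hidden_conditional(batch, p)
    if hidden_mask is not None:
        pos_hm = pos_hm * hidden_mask
    v = batch
    for step in range(cd_steps):
        hm, hs = hidden_conditional(v, p, None if mean_field else rng)
        if mean_field:
            hs = hm
        if hidden_mask is not None:
            hs = hs * hidden_mask
        if sample_visible and not mean_field:
            _, v = visible_conditional(hs, p, rng)
        else:
            v = visible_mean(hs, p)
    neg_hm, _ = hidden_conditional(v, p)
    if hidden_mask is not None:
        neg_hm = neg_hm * hidden_mask
    pos = _stats(batch, pos_hm, p)
    neg = _stats(v, neg_hm, p)
    return Gradients(dW=pos.dW - neg.dW, da=pos.da - neg.da, db=pos.db - neg.db)


def update_step(p: RBMParams, grad: Gradients, cfg: TrainConfig) -> RBMParams:
    """One L1-regularized ascent step:
    W <- W + eps * (dW - lambda * sgn(W)), biases without decay.
    np.sign gives sgn(0) = 0, so zero weights feel no decay."""
    W = p.W + cfg.epsilon * (grad.dW - cfg.lambda_l1 * np.sign(p.W))
    return replace(p, W=W, a=p.a + cfg.epsilon * grad.da,
                   b=p.b + cfg.epsilon * grad.db)


def reconstruction_error(data: np.ndarray, p: RBMParams) -> float:
    """Mean squared error between the data and its one-step mean
    reconstruction through the hidden means."""
    hm, _ = hidden_conditional(data, p)
    return float(np.mean((visible_mean(hm, p) - data) ** 2))


def train_rbm(
    data,
    n_hidden: int,
    cfg: TrainConfig,
    hidden_type: str = "tanh",
    visible_type: str = "gaussian",
    params: RBMParams | None = None,
    standard_form: bool = False,
) -> tuple[RBMParams, TrainLog]:
    """Mini-batch CD training with the L1-regularized update rule.

    ``data`` is an (n_samples, n_visible) array (voxels expected z-scored
    for Gaussian visibles) or anything with a ``.values`` attribute holding
    one.  Deterministic given ``cfg.seed``.

    By default Gaussian-visible models are trained under the no-1/2 energy
    convention (``standard_form=False``), whose visible reconstruction gain
    of sigma/2 keeps CD-1 numerically stable at the reference learning rate
    of 0.08 on z-scored voxel data; the textbook convention (gain sigma) is
    available but needs a learning rate roughly an order of magnitude
    smaller before it stops diverging at realistic voxel counts.
    """
    X = np.asarray(getattr(data, "values", data), float)
    if np.isnan(X).any():
        raise ValueError("data contains NaN")
    n, V = X.shape
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_params(V, n_hidden, seed=cfg.seed,
                             hidden_type=hidden_type, visible_type=visible_type,
                             standard_form=standard_form)
    log = TrainLog()
    keep_v = 1.0 - cfg.dropout_visible
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            if cfg.dropout_visible > 0:
                batch = batch * (rng.random(batch.shape) < keep_v)
            hmask = None
            if cfg.dropout_hidden > 0:
                hmask = (rng.random(n_hidden) < 1.0 - cfg.dropout_hidden).astype(float)
            grad = cd_gradient(batch, params, cfg.cd_steps, rng, hidden_mask=hmask)
            params = update_step(params, grad, cfg)
            log.n_updates += 1
        log.recon_error.append(reconstruction_error(X, params))
        log.mean_abs_w.append(float(np.abs(params.W).mean()))
    return params, log


# ---------------------------------------------------------------------------
# exact enumeration oracle (tiny models only)


def _hidden_states(p: RBMParams) -> np.ndarray:
    if p.n_hidden > 12:
        raise ValueError("exact enumeration limited to n_hidden <= 12")
    vals = (-1.0, 1.0) if p.hidden_type == "tanh" else (0.0, 1.0)
    return np.array(list(product(vals, repeat=p.n_hidden)))


def _free_terms(p: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """For each enumerated hidden state h: the visible drive c = W^T h and
    the log of the h-marginal weight exp(b.h + sum_j a_j c_j / sigma_j +
    c_j^2 / 2) obtained by integrating the Gaussian visibles out
    (standard-form energy)."""
    S = _hidden_states(p)                      # (2^H, H)
    C = S @ p.W                                # (2^H, V)
    logw = S @ p.b + C @ (p.a / p.sigma) + 0.5 * (C**2).sum(axis=1)
    return C, logw


def exact_log_z(p: RBMParams) -> float:
    if p.visible_type != "gaussian" or not p.standard_form:
        raise ValueError("oracle supports standard-form Gaussian visibles")
    _, logw = _free_terms(p)
    const = 0.5 * np.sum(np.log(2.0 * np.pi * p.sigma**2))
    return float(logsumexp(logw) + const)


def exact_loglik(p: RBMParams, data: np.ndarray) -> float:
    """Exact mean log-likelihood of the data under a tiny RBM."""
    X = np.atleast_2d(np.asarray(data, float))
    S = _hidden_states(p)
    Z = hidden_preactivation(X, p)             # (n, H)
    quad = -0.5 * (((X - p.a) / p.sigma) ** 2).sum(axis=1)
    un = quad + logsumexp(Z @ S.T, axis=1)
    return float(un.mean() - exact_log_z(p))


def exact_gradient_oracle(p: RBMParams, data: np.ndarray) -> Gradients:
    """Exact gradient of the mean log-likelihood, by enumerating the 2^H
    hidden states and integrating the Gaussian visibles in closed form."""
    X = np.atleast_2d(np.asarray(data, float))
    if p.visible_type != "gaussian" or not p.standard_form:
        raise ValueError("oracle supports standard-form Gaussian visibles")
    S = _hidden_states(p)
    # data (positive) term: hidden means given each data vector
    hm, _ = hidden_conditional(X, p)
    pos = _stats(X, hm, p)
    # model (negative) term: expectation under the joint
    C, logw = _free_terms(p)
    P = np.exp(logw - logsumexp(logw))         # (2^H,)
    mu = p.a + p.sigma * C                     # E[v | h] per state
    dW = (S * P[:, None]).T @ (mu / p.sigma)   # E[h v/sigma]
    da = P @ ((mu - p.a) / p.sigma**2)
    db = P @ S
    return Gradients(dW=pos.dW - dW, da=pos.da - da, db=pos.db - db)


# ---------------------------------------------------------------------------
# feature post-processing


def project_timecourses(
    data: np.ndarray, p: RBMParams, apply_nonlinearity: bool = False
) -> np.ndarray:
    """Project data into feature space: one time course per hidden unit.

    Without the nonlinearity this is the plain linear projection
    z = data W^T / sigma + b (the convention for comparing against ground
    truth time courses); with it, the hidden unit's nonlinearity is applied
    elementwise (the feed-forward convention used when stacking).
    """
    z = hidden_preactivation(data, p)
    if not apply_nonlinearity:
        return z
    return np.tanh(z) if p.hidden_type == "tanh" else expit(z)


def flip_negative_features(p: RBMParams) -> tuple[RBMParams, np.ndarray]:
    """Resolve the sign ambiguity of the receptive fields.

    A feature row is multiplied by -1 iff the mean of its suprathreshold
    entries (|w| > 2 standard deviations of the row) is negative.  Time
    courses recomputed through the flipped weights acquire the correct sign
    automatically; only the maps are flipped explicitly.
    """
    W = p.W.copy()
    mask = np.zeros(p.n_hidden, dtype=bool)
    for i in range(p.n_hidden):
        row = W[i]
        thresh = 2.0 * row.std()
        supra = row[np.abs(row) > thresh]
        if supra.size and supra.mean() < 0:
            W[i] = -row
            mask[i] = True
    return replace(p, W=W), mask
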