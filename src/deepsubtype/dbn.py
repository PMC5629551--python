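"""Bernoulli RBM stack with contrastive-divergence pre-training, unfolded
into a deep autoencoder and fine-tuned by cross-entropy backpropagation.

The model family: a restricted Boltzmann machine over binary visible units v
and binary hidden units h with energy

    E(v, h) = -(h^T W v + c^T v + b^T h)

and Boltzmann joint P(v, h) = exp(-E(v, h)) / Z.  Pre-training maximizes the
marginal likelihood of the data layer-by-layer with CD-k (default k=1):
hidden states are sampled stochastically on the data-driven Gibbs step,
while sufficient statistics use mean-field probabilities.  The trained stack
is then unfolded into an encoder/decoder pair (weights untied from that
point) and fine-tuned end-to-end with plain minibatch SGD on the mean binary
cross-entropy between input and reconstruction; all units are logistic.

For tiny RBMs (<= 20 total units) the exact joint distribution, partition
function, log-likelihood and likelihood gradient are available by full state
enumeration -- these serve as correctness oracles for the sampled learner.

A statsmodels-style front end is provided: :class:`DeepBeliefNetwork` is
built from a (samples x genes) binary matrix and ``fit()`` returns a
:class:`DbnResults` with the trained parameters, training log, encoder, and
a ``summary()`` table.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

_EPS = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# RBM parameters and exact (enumeration) oracles
# ---------------------------------------------------------------------------

@dataclass
class RbmParams:
    """RBM parameters: W is hidden x visible, b hidden offsets, c visible
    offsets (energy E = -(h^T W v + c^T v + b^T h))."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        nh, nv = self.W.shape
        if self.b.shape != (nh,) or self.c.shape != (nv,):
            raise ValueError("offset shapes inconsistent with W")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()
                and np.isfinite(self.c).all()):
            raise ValueError("non-finite RBM parameters")

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "RbmParams":
        return RbmParams(self.W.copy(), self.b.copy(), self.c.copy())


def rbm_energy(v: np.ndarray, h: np.ndarray, p: RbmParams) -> float:
    """E(v, h) = -(h^T W v + c^T v + b^T h)."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.shape != (p.n_visible,) or h.shape != (p.n_hidden,):
        raise ValueError("state dimensions do not match parameters")
    return float(-(h @ p.W @ v + p.c @ v + p.b @ h))


def _all_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, lexicographic (bit 0 = column 0)."""
    idx = np.arange(2 ** n)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


def rbm_exact_distribution(p: RbmParams):
    """Exact joint P(v, h) by full enumeration (<= 20 total units).

    Returns (V, H, P) where V is (2^nv, nv), H is (2^nh, nh) and P[i, j] is
    the probability of (V[i], H[j]); P sums to 1.
    """
    if p.n_visible + p.n_hidden > 20:
        raise ValueError("state space too large for enumeration (> 20 units)")
    V = _all_states(p.n_visible)
    H = _all_states(p.n_hidden)
    # E[i,j] for v=V[i], h=H[j]
    energy = -(H @ p.W @ V.T).T - (V @ p.c)[:, None] - (H @ p.b)[None, :]
    logp = -energy
    logp -= logp.max()
    P = np.exp(logp)
    P /= P.sum()
    return V, H, P


def rbm_free_energy(v: np.ndarray, p: RbmParams) -> np.ndarray:
    """F(v) = -c^T v - sum_j log(1 + exp(W v + b)_j); log P(v) = -F(v) - log Z."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    act = v @ p.W.T + p.b
    return -(v @ p.c) - np.logaddexp(0.0, act).sum(axis=1)


def rbm_log_partition(p: RbmParams) -> float:
    """log Z by enumeration over visible states (tiny RBMs only)."""
    if p.n_visible + p.n_hidden > 24:
        raise ValueError("state space too large for enumeration")
    V = _all_states(p.n_visible)
    from scipy.special import logsumexp
    return float(logsumexp(-rbm_free_energy(V, p)))


def rbm_exact_loglik(data: np.ndarray, p: RbmParams) -> float:
    """Mean exact log-likelihood of the rows of ``data`` (enumeration)."""
    logz = rbm_log_partition(p)
    return float(np.mean(-rbm_free_energy(data, p) - logz))


def rbm_exact_gradient(v: np.ndarray, p: RbmParams):
    """Exact gradient of log P(v) w.r.t. (W, b, c) for a single datapoint,
    via d log P / d W = E_{h|v}[h v^T] - E_{v,h}[h v^T] (enumeration)."""
    v = np.asarray(v, dtype=float).ravel()
    ph = _sigmoid(p.W @ v + p.b)
    V, H, P = rbm_exact_distribution(p)
    # model expectations
    e_hv = np.einsum("ij,jk,il->kl", P, H, V)   # hidden x visible
    e_h = P.sum(axis=0) @ H
    e_v = P.sum(axis=1) @ V
    return np.outer(ph, v) - e_hv, ph - e_h, v - e_v


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for pre-training and fine-tuning one DBN.

    ``layer_sizes`` are the hidden layer sizes bottom-up; decreasing sizes
    are conventional but not enforced here (model selection enforces its own
    structural constraints).
    """

    layer_sizes: tuple[int, ...] = (60, 25, 10)
    lr_pretrain: float = 0.05
    lr_finetune: float = 0.05
    epochs_pretrain: int = 30
    epochs_finetune: int = 60
    batch_size: int = 100
    cd_steps: int = 1
    momentum: float = 0.0
    weight_decay: float = 0.0
    init_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) == 0 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be nonempty positive ints")
        if self.lr_pretrain < 0 or self.lr_finetune < 0:
            raise ValueError("learning rates must be >= 0")
        if self.epochs_pretrain < 0 or self.epochs_finetune < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1 or self.cd_steps < 1:
            raise ValueError("batch_size and cd_steps must be >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Contrastive-divergence pre-training
# ---------------------------------------------------------------------------

def rbm_train_cd(
    data: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
    init: RbmParams | None = None,
) -> RbmParams:
    """Train one Bernoulli RBM with minibatch CD-k.

    Positive phase samples binary hidden states; negative-phase visible and
    hidden statistics use mean-field probabilities.  ``init`` warm-starts
    from existing parameters instead of the seeded Gaussian init.  Raises if
    parameters go non-finite (learning rate too high).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (samples x visible)")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    n, nv = data.shape
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    if init is not None:
        if init.W.shape != (n_hidden, nv):
            raise ValueError("init shape does not match data/n_hidden")
        W, b, c = init.W.copy(), init.b.copy(), init.c.copy()
    else:
        W = rng.normal(0.0, cfg.init_sd, size=(n_hidden, nv))
        b = np.zeros(n_hidden)
        c = np.zeros(nv)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    vc = np.zeros_like(c)
    bs = min(cfg.batch_size, n)

    for _ in range(cfg.epochs_pretrain):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            V = data[order[start:start + bs]]
            m = len(V)
            ph = _sigmoid(V @ W.T + b)
            h = (rng.random(ph.shape) < ph).astype(float)
            for _k in range(cfg.cd_steps):
                pv = _sigmoid(h @ W + c)
                ph_neg = _sigmoid(pv @ W.T + b)
                if _k < cfg.cd_steps - 1:
                    h = (rng.random(ph_neg.shape) < ph_neg).astype(float)
            gW = (ph.T @ V - ph_neg.T @ pv) / m - cfg.weight_decay * W
            gb = (ph - ph_neg).mean(axis=0)
            gc = (V - pv).mean(axis=0)
            vW = cfg.momentum * vW + cfg.lr_pretrain * gW
            vb = cfg.momentum * vb + cfg.lr_pretrain * gb
            vc = cfg.momentum * vc + cfg.lr_pretrain * gc
            W += vW
            b += vb
            c += vc
        if not (np.isfinite(W).all() and np.isfinite(b).all() and np.isfinite(c).all()):
            raise RuntimeError(
                "NaN/Inf in RBM parameters during CD training; "
                "reduce lr_pretrain"
            )
    return RbmParams(W, b, c)


def stack_pretrain(
    data: np.ndarray, cfg: TrainConfig, rng: np.random.Generator | None = None
) -> list[RbmParams]:
    """Greedy layer-wise pre-training: RBM L is trained on the hidden
    activation *probabilities* of RBM L-1 applied to the data."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    x = np.asarray(data, dtype=float)
    rbms: list[RbmParams] = []
    for size in cfg.layer_sizes:
        p = rbm_train_cd(x, size, cfg, rng=rng)
        rbms.append(p)
        x = _sigmoid(x @ p.W.T + p.b)
    return rbms


# ---------------------------------------------------------------------------
# Unfolded autoencoder and fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class DbnModel:
    """Unfolded deep autoencoder.

    ``encoder``/``decoder`` are lists of (A, bias) with activation
    ``sigmoid(X @ A + bias)``; decoder weights start as transposed copies of
    the encoder's (tied initialization) and are untied from unfolding on.
    ``training_log`` records per-epoch cross-entropy and MSE.
    """

    encoder: list[tuple[np.ndarray, np.ndarray]]
    decoder: list[tuple[np.ndarray, np.ndarray]]
    layer_sizes: tuple[int, ...]
    gene_ids: list[str] | None = None
    training_log: dict = field(default_factory=lambda: {
        "finetune_cross_entropy": [], "finetune_mse": []})

    @property
    def n_visible(self) -> int:
        return self.encoder[0][0].shape[0]

    def encode(self, data: np.ndarray) -> np.ndarray:
        x = np.asarray(data, dtype=float)
        for A, bias in self.encoder:
            x = _sigmoid(x @ A + bias)
        return x

    def reconstruct(self, data: np.ndarray) -> np.ndarray:
        x = self.encode(data)
        for A, bias in self.decoder:
            x = _sigmoid(x @ A + bias)
        return x

    def copy(self) -> "DbnModel":
        return DbnModel(
            encoder=[(A.copy(), bb.copy()) for A, bb in self.encoder],
            decoder=[(A.copy(), bb.copy()) for A, bb in self.decoder],
            layer_sizes=tuple(self.layer_sizes),
            gene_ids=list(self.gene_ids) if self.gene_ids else None,
            training_log={k: list(v) for k, v in self.training_log.items()},
        )

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["layer_sizes"] = list(self.layer_sizes)
            if self.gene_ids is not None:
                f.create_dataset("gene_ids",
                                 data=np.array(self.gene_ids, dtype="S"))
            for name, layers in [("encoder", self.encoder),
                                 ("decoder", self.decoder)]:
                grp = f.create_group(name)
                for i, (A, bias) in enumerate(layers):
                    grp.create_dataset(f"W{i}", data=A)
                    grp.create_dataset(f"b{i}", data=bias)
            f.attrs["training_log"] = json.dumps(self.training_log)

    @classmethod
    def load(cls, path: str | Path) -> "DbnModel":
        with h5py.File(path, "r") as f:
            def _layers(name):
                grp = f[name]
                out = []
                for i in range(len(grp) // 2):
                    out.append((grp[f"W{i}"][...], grp[f"b{i}"][...]))
                return out
            gene_ids = None
            if "gene_ids" in f:
                gene_ids = [g.decode() for g in f["gene_ids"][...]]
            return cls(
                encoder=_layers("encoder"),
                decoder=_layers("decoder"),
                layer_sizes=tuple(int(s) for s in f.attrs["layer_sizes"]),
                gene_ids=gene_ids,
                training_log=json.loads(f.attrs["training_log"]),
            )


def unfold(rbms: list[RbmParams], gene_ids: list[str] | None = None) -> DbnModel:
    """Unfold a pre-trained stack into an autoencoder.

    Encoder layer L uses W_L^T with hidden offsets; decoder mirrors the stack
    top-down with W_L and visible offsets.  All matrices are independent
    copies (untied)."""
    if not rbms:
        raise ValueError("need at least one RBM")
    encoder = [(p.W.T.copy(), p.b.copy()) for p in rbms]
    decoder = [(p.W.copy(), p.c.copy()) for p in reversed(rbms)]
    return DbnModel(encoder=encoder, decoder=decoder,
                    layer_sizes=tuple(p.n_hidden for p in rbms),
                    gene_ids=gene_ids)


def cross_entropy(model: DbnModel, data: np.ndarray) -> float:
    """Mean binary cross-entropy per (sample, unit) between data and its
    reconstruction."""
    y = np.asarray(data, dtype=float)
    p = np.clip(model.reconstruct(y), _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def reconstruction_error(model: DbnModel, data: np.ndarray) -> float:
    """Mean squared error between data and its reconstruction."""
    y = np.asarray(data, dtype=float)
    return float(np.mean((y - model.reconstruct(y)) ** 2))


def finetune(
    model: DbnModel,
    data: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
    eval_data: np.ndarray | None = None,
) -> DbnModel:
    """Fine-tune the unfolded autoencoder by minibatch SGD on binary
    cross-entropy (backpropagation; deterministic logistic probabilities
    throughout).

    Returns a new model; the input model is untouched.  The training log
    gains per-epoch ``finetune_cross_entropy`` and ``finetune_mse`` on the
    training data and, when ``eval_data`` is given, ``eval_mse`` /
    ``eval_cross_entropy``.  Aborts if cross-entropy exceeds 10x its initial
    value (divergence).
    """
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    m = model.copy()
    layers = m.encoder + m.decoder  # forward order
    n = data.shape[0]
    bs = min(cfg.batch_size, n)

    vel = [(np.zeros_like(A), np.zeros_like(bias)) for A, bias in layers]
    initial_ce = cross_entropy(m, data)
    if eval_data is not None:
        m.training_log.setdefault("eval_mse", [])
        m.training_log.setdefault("eval_cross_entropy", [])

    for _ in range(cfg.epochs_finetune):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            X = data[order[start:start + bs]]
            mb = len(X)
            acts = [X]
            a = X
            for A, bias in layers:
                a = _sigmoid(a @ A + bias)
                acts.append(a)
            # output delta for sigmoid + cross-entropy
            # (loss = mean over batch, sum over units -- lr is then
            # comparable across input widths in the usual convention)
            delta = (acts[-1] - X) / mb
            for li in range(len(layers) - 1, -1, -1):
                A, bias = layers[li]
                gA = acts[li].T @ delta + cfg.weight_decay * A
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ A.T) * acts[li] * (1 - acts[li])
                vA = cfg.momentum * vel[li][0] - cfg.lr_finetune * gA
                vb = cfg.momentum * vel[li][1] - cfg.lr_finetune * gb
                vel[li] = (vA, vb)
                layers[li] = (A + vA, bias + vb)
        ne = len(m.encoder)
        m.encoder = layers[:ne]
        m.decoder = layers[ne:]
        ce = cross_entropy(m, data)
        m.training_log["finetune_cross_entropy"].append(ce)
        m.training_log["finetune_mse"].append(reconstruction_error(m, data))
        if eval_data is not None:
            m.training_log["eval_mse"].append(reconstruction_error(m, eval_data))
            m.training_log["eval_cross_entropy"].append(cross_entropy(m, eval_data))
        # divergence: >10x worse than the starting point, with the trivial
        # p=0.5 predictor (CE = ln 2) as a floor so a well pre-trained model
        # is not aborted over a transient SGD spike
        if not np.isfinite(ce) or ce > 10 * max(initial_ce, np.log(2)):
            raise RuntimeError(
                f"fine-tuning diverged (cross-entropy {ce:.4g} vs initial "
                f"{initial_ce:.4g}); reduce lr_finetune"
            )
    return m


def encode(model: DbnModel, data: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Deterministic forward pass to the top hidden layer.

    DataFrame inputs are checked (and reordered) against the model's
    training gene ids."""
    if isinstance(data, pd.DataFrame):
        if model.gene_ids is not None:
            if set(data.columns) != set(model.gene_ids):
                raise ValueError("input gene ids do not match the model's "
                                 "training genes")
            data = data.loc[:, model.gene_ids]
        data = data.to_numpy()
    return model.encode(data)


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class DeepBeliefNetwork:
    """Deep belief network over a binary (samples x genes) matrix.

    Parameters
    ----------
    data : DataFrame or ndarray
        Binary aberration matrix, one row per tumor.
    layer_sizes : sequence of int
        Hidden layer sizes, bottom-up; the last is the representation used
        for clustering.
    config : TrainConfig, optional
        Full hyperparameter set; ``layer_sizes`` overrides its field.
    """

    def __init__(self, data, layer_sizes=(60, 25, 10),
                 config: TrainConfig | None = None):
        if isinstance(data, pd.DataFrame):
            self.gene_ids = list(data.columns)
            self.sample_ids = list(data.index)
            self.endog = data.to_numpy(dtype=float)
        else:
            self.gene_ids = None
            self.sample_ids = None
            self.endog = np.asarray(data, dtype=float)
        if self.endog.ndim != 2:
            raise ValueError("data must be 2-D")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("data must be binary (0/1)")
        base = config or TrainConfig()
        self.config = base.replace(layer_sizes=tuple(int(s) for s in layer_sizes))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, layer_sizes=(60, 25, 10),
                       **config_kw) -> "DeepBeliefNetwork":
        return cls(df, layer_sizes=layer_sizes,
                   config=TrainConfig(layer_sizes=tuple(layer_sizes), **config_kw))

    def fit(self, seed: int | None = None) -> "DbnResults":
        """Pre-train the RBM stack, unfold, fine-tune; return results."""
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        rng = np.random.default_rng(cfg.seed)
        rbms = stack_pretrain(self.endog, cfg, rng=rng)
        model = unfold(rbms, gene_ids=self.gene_ids)
        model = finetune(model, self.endog, cfg, rng=rng)
        return DbnResults(self, model, rbms, cfg)


class DbnResults:
    """Fitted DBN: trained autoencoder, pre-trained stack, and diagnostics."""

    def __init__(self, model_spec: DeepBeliefNetwork, model: DbnModel,
                 rbms: list[RbmParams], config: TrainConfig):
        self.model_spec = model_spec
        self.model = model
        self.rbms = rbms
        self.config = config

    @property
    def training_log(self) -> dict:
        return self.model.training_log

    def encode(self, data=None) -> pd.DataFrame:
        if data is None:
            z = self.model.encode(self.model_spec.endog)
            idx = self.model_spec.sample_ids
        else:
            z = encode(self.model, data)
            idx = list(data.index) if isinstance(data, pd.DataFrame) else None
        cols = [f"h{j}" for j in range(z.shape[1])]
        return pd.DataFrame(z, index=idx, columns=cols)

    def reconstruction_error(self, data=None) -> float:
        x = self.model_spec.endog if data is None else np.asarray(data, float)
        return reconstruction_error(self.model, x)

    def cross_entropy(self, data=None) -> float:
        x = self.model_spec.endog if data is None else np.asarray(data, float)
        return cross_entropy(self.model, x)

    def save(self, path: str | Path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        log = self.training_log
        buf = io.StringIO()
        n, g = self.model_spec.endog.shape
        buf.write("Deep Belief Network (stacked RBM autoencoder)\n")
        buf.write("=" * 52 + "\n")
        buf.write(f"Samples: {n}    Visible units (genes): {g}\n")
        buf.write(f"Hidden layers: {'-'.join(map(str, self.config.layer_sizes))}\n")
        buf.write(f"Pre-training: CD-{self.config.cd_steps}, "
                  f"lr={self.config.lr_pretrain:g}, "
                  f"epochs={self.config.epochs_pretrain}\n")
        buf.write(f"Fine-tuning:  SGD, lr={self.config.lr_finetune:g}, "
                  f"epochs={self.config.epochs_finetune}, "
                  f"batch={self.config.batch_size}\n")
        if log["finetune_cross_entropy"]:
            buf.write(f"Final cross-entropy (per unit): "
                      f"{log['finetune_cross_entropy'][-1]:.6f}\n")
            buf.write(f"Final reconstruction MSE:       "
                      f"{log['finetune_mse'][-1]:.6f}\n")
        return buf.getvalue()
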