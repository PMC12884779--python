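"""Adversarial deconfounding autoencoder.

An encoder f and decoder g are trained to reconstruct log-normalized
expression while an adversary h is trained to predict a nuisance label
(study/batch/tissue) from the latent code z = f(x). Training alternates:

1. pretrain the autoencoder on reconstruction (plus a mixture-consistency
   term that makes the encoder linear over convex combinations of cells in
   CP10K space, so bulk mixtures embed where the deconvolution model
   expects them);
2. pretrain the adversary on the frozen embeddings;
3. joint rounds — one autoencoder epoch minimizing reconstruction while
   pushing the frozen adversary's predictions toward uniform (the bounded
   surrogate for maximizing its loss, with the adversarial gradient
   norm-capped against the reconstruction gradient), then several adversary
   epochs with the autoencoder frozen. The round on which the adversary was
   most confused is checkpointed and returned, and training stops early
   once the adversary holds at chance.

The result is a latent space in which the confounder is no longer decodable
but cell identity is, shared by reference cells and bulk samples alike.

Networks are small fully-connected stacks (ReLU hidden layers, linear latent
and output, softmax adversary head) with hand-written backpropagation and an
Adam optimizer on plain numpy arrays; every weight draw and batch shuffle
flows from the config seed, so runs are reproducible on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


# ---------------------------------------------------------------------------
# minimal MLP machinery
# ---------------------------------------------------------------------------


class _MLP:
    """Fully-connected net, ReLU hidden layers, linear output, Adam updates."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.dims = list(dims)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0
        self._cache: list[np.ndarray] | None = None

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        if cache:
            self._cache = acts
        return h

    def backward(self, d_out: np.ndarray) -> tuple[np.ndarray, list, list]:
        """Gradient of loss w.r.t. input and parameters, given dL/d_output."""
        acts = self._cache
        if acts is None:
            raise RuntimeError("forward(cache=True) must precede backward")
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        d = d_out
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                d = d * (acts[i + 1] > 0)
            dW[i] = acts[i].T @ d
            db[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return d, dW, db

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]

    def adam_step(
        self, dW: list, db: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self._adam_t += 1
        if weight_decay:
            dW = [g + weight_decay * w for g, w in zip(dW, self.W)]
        grads = dW + db
        params = self.W + self.b
        for j, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[j] = beta1 * self._adam_m[j] + (1 - beta1) * g
            self._adam_v[j] = beta2 * self._adam_v[j] + (1 - beta2) * g * g
            mhat = self._adam_m[j] / (1 - beta1**self._adam_t)
            vhat = self._adam_v[j] / (1 - beta2**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# parameter containers and config
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Training schedule and architecture.

    ``lambda_`` is the adversarial weight (1 in the published sensitivity
    plateau); the latent size defaults to 100 dimensions. Hidden widths,
    optimizer and epoch counts are package defaults sized for CPU training.
    """

    d_latent: int = 100
    hidden: tuple[int, ...] = (512, 256)
    adv_hidden: tuple[int, ...] = ()
    lambda_: float = 1.0
    learning_rate: float = 1e-3
    adv_learning_rate: float = 1e-3
    adv_weight_decay: float = 0.0
    adv_grad_cap: float = 1.0
    batch_size: int = 128
    ae_pretrain_epochs: int = 50
    adv_pretrain_epochs: int = 20
    joint_rounds: int = 30
    adv_epochs_per_round: int = 5
    adv_stop_margin: float | None = 0.05
    adv_stop_patience: int = 3
    min_joint_rounds: int = 10
    input_scaling: str = "center"  # "zscore" | "center" | "none"
    mix_weight: float = 1.0
    mix_per_batch: int = 16
    mix_cells: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        for name in ("ae_pretrain_epochs", "adv_pretrain_epochs", "joint_rounds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EncoderDecoderParams:
    """Trained encoder/decoder with the gene order and scaling they expect.

    Inputs are standardized per gene (mean/sd learned from the training
    cells) before entering the encoder; reconstruction targets the
    standardized profile. ``encode`` and ``embed_bulk`` are the same function
    applied to reference cells and bulk samples.
    """

    encoder: _MLP
    decoder: _MLP
    gene_ids: np.ndarray
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    architecture: dict = field(default_factory=dict)

    @property
    def d_latent(self) -> int:
        return self.encoder.dims[-1]


@dataclass
class AdversaryParams:
    """Adversary network mapping latent codes to confounder-class probabilities."""

    net: _MLP
    classes: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class ConfounderLabels:
    """A named categorical nuisance annotation, one label per training cell."""

    name: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.classes = np.array(sorted(set(self.labels.astype(str))), dtype=object)

    def one_hot(self, classes: np.ndarray | None = None) -> np.ndarray:
        classes = self.classes if classes is None else classes
        lut = {c: i for i, c in enumerate(classes)}
        unseen = [l for l in set(self.labels.astype(str)) if l not in lut]
        if unseen:
            raise ValueError(f"labels contain unseen classes: {unseen}")
        Y = np.zeros((len(self.labels), len(classes)))
        Y[np.arange(len(self.labels)), [lut[l] for l in self.labels.astype(str)]] = 1.0
        return Y


# ---------------------------------------------------------------------------
# losses and inference
# ---------------------------------------------------------------------------


def init_params(n_genes: int, cfg: TrainingConfig, gene_ids=None) -> EncoderDecoderParams:
    rng = np.random.default_rng(cfg.seed)
    enc = _MLP([n_genes, *cfg.hidden, cfg.d_latent], rng)
    dec = _MLP([cfg.d_latent, *reversed(cfg.hidden), n_genes], rng)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    return EncoderDecoderParams(
        encoder=enc,
        decoder=dec,
        gene_ids=np.asarray(gene_ids, dtype=object),
        gene_mean=np.zeros(n_genes),
        gene_sd=np.ones(n_genes),
        architecture={
            "hidden": list(cfg.hidden),
            "d_latent": cfg.d_latent,
            "activation": "relu",
        },
    )


def init_adversary(cfg: TrainingConfig, classes: np.ndarray) -> AdversaryParams:
    rng = np.random.default_rng(cfg.seed + 1)
    net = _MLP([cfg.d_latent, *cfg.adv_hidden, len(classes)], rng)
    return AdversaryParams(net=net, classes=np.asarray(classes, dtype=object))


def _check_genes(params: EncoderDecoderParams, gene_ids) -> None:
    if gene_ids is None:
        return
    gene_ids = np.asarray(gene_ids, dtype=object)
    if len(gene_ids) != len(params.gene_ids) or (gene_ids != params.gene_ids).any():
        raise ValueError("gene order does not match the panel the encoder was trained on")


def _standardize(params: EncoderDecoderParams, X: np.ndarray) -> np.ndarray:
    return (X - params.gene_mean) / params.gene_sd


def encode(
    params: EncoderDecoderParams, expr: np.ndarray, gene_ids=None
) -> np.ndarray:
    """Map expression rows (samples/cells x panel genes) to latent rows."""
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    _check_genes(params, gene_ids)
    if expr.shape[1] != len(params.gene_ids):
        raise ValueError(
            f"expected {len(params.gene_ids)} panel genes, got {expr.shape[1]}"
        )
    return params.encoder.forward(_standardize(params, expr))


def embed_bulk(params: EncoderDecoderParams, expr: np.ndarray, gene_ids=None) -> np.ndarray:
    """Embed bulk samples with the trained encoder (same map as ``encode``)."""
    return encode(params, expr, gene_ids=gene_ids)


def reconstruction_loss(params: EncoderDecoderParams, expr: np.ndarray) -> float:
    """Mean over rows of the squared 2-norm between input and reconstruction."""
    X = _standardize(params, np.atleast_2d(np.asarray(expr, dtype=float)))
    Xhat = params.decoder.forward(params.encoder.forward(X))
    return float(((X - Xhat) ** 2).sum(axis=1).mean())


def adversary_loss(
    adv: AdversaryParams, latents: np.ndarray, labels: ConfounderLabels
) -> float:
    """Mean categorical cross-entropy of the adversary on given latents."""
    Y = labels.one_hot(adv.classes)
    P = _softmax(adv.net.forward(np.atleast_2d(latents)))
    return float(-(Y * np.log(np.clip(P, 1e-12, None))).sum(axis=1).mean())


def adversary_accuracy(
    adv: AdversaryParams, latents: np.ndarray, labels: ConfounderLabels
) -> float:
    P = _softmax(adv.net.forward(np.atleast_2d(latents)))
    lut = {c: i for i, c in enumerate(adv.classes)}
    y = np.array([lut[l] for l in labels.labels.astype(str)])
    return float((P.argmax(axis=1) == y).mean())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _check_finite(value: float, what: str) -> None:
    if not np.isfinite(value):
        raise TrainingDivergedError(f"{what} became non-finite ({value})")


def _mixture_grads(
    params: "EncoderDecoderParams",
    raw_batch: np.ndarray,
    z_batch: np.ndarray,
    cfg: "TrainingConfig",
    rng: np.random.Generator,
):
    """Encoder gradients of the mixture-consistency term for one batch.

    Synthetic pseudo-mixtures are formed in linear (CP10K) space — the space
    in which bulk profiles are sums of cells — and the encoder is trained so
    the mixture's latent code equals the same convex combination of its
    members' codes (targets are held fixed). ``raw_batch`` should hold the
    cells' *unsmoothed* log-normalized profiles when available, so the
    mixtures resemble real pseudobulks while the targets stay anchored to
    the (smoothed) reference embeddings. This is what licenses reading bulk
    embeddings as T ~= P R later on.
    """
    b = len(raw_batch)
    m = min(cfg.mix_cells, b)
    members = rng.integers(0, b, size=(cfg.mix_per_batch, m))
    W = np.zeros((cfg.mix_per_batch, b))
    rows = np.repeat(np.arange(cfg.mix_per_batch), m)
    np.add.at(W, (rows, members.ravel()), 1.0 / m)
    xm = _standardize(params, np.log1p(W @ np.expm1(raw_batch)))
    zm = params.encoder.forward(xm, cache=True)
    target = W @ z_batch  # treated as constant (no gradient through members)
    d_zm = 2.0 * cfg.mix_weight * (zm - target) / zm.size
    _, dWe, dbe = params.encoder.backward(d_zm)
    loss = float(cfg.mix_weight * ((zm - target) ** 2).mean())
    return dWe, dbe, loss


def pretrain_autoencoder(
    data: np.ndarray, cfg: TrainingConfig, gene_ids=None, mix_source: np.ndarray | None = None
) -> tuple[EncoderDecoderParams, list[float]]:
    """Step (i): train encoder+decoder on reconstruction alone.

    ``data`` is cells x panel-genes log-normalized expression. The squared
    error is averaged over genes inside the optimized objective so that the
    adversarial weight keeps the same meaning for any panel size; the
    reported ``reconstruction_loss`` remains the per-row squared 2-norm.
    """
    data = np.asarray(data, dtype=float)
    mix_source = data if mix_source is None else np.asarray(mix_source, dtype=float)
    n, g = data.shape
    params = init_params(g, cfg, gene_ids=gene_ids)
    if cfg.input_scaling in ("zscore", "center"):
        params.gene_mean = data.mean(axis=0)
    if cfg.input_scaling == "zscore":
        sd = data.std(axis=0)
        params.gene_sd = np.where(sd == 0, 1.0, sd)
    X = _standardize(params, data)
    rng = np.random.default_rng(cfg.seed + 2)
    history: list[float] = []
    for _ in range(cfg.ae_pretrain_epochs):
        for idx in _batches(n, cfg.batch_size, rng):
            xb = X[idx]
            z = params.encoder.forward(xb, cache=True)
            xhat = params.decoder.forward(z, cache=True)
            d_out = 2.0 * (xhat - xb) / (len(idx) * g)
            dz, dWd, dbd = params.decoder.backward(d_out)
            _, dWe, dbe = params.encoder.backward(dz)
            if cfg.mix_weight > 0:
                dWm, dbm, _ = _mixture_grads(params, mix_source[idx], z, cfg, rng)
                dWe = [a + b_ for a, b_ in zip(dWe, dWm)]
                dbe = [a + b_ for a, b_ in zip(dbe, dbm)]
            params.decoder.adam_step(dWd, dbd, cfg.learning_rate)
            params.encoder.adam_step(dWe, dbe, cfg.learning_rate)
        epoch_loss = reconstruction_loss(params, data)
        _check_finite(epoch_loss, "reconstruction loss")
        history.append(epoch_loss)
    return params, history


def pretrain_adversary(
    params: EncoderDecoderParams,
    data: np.ndarray,
    labels: ConfounderLabels,
    cfg: TrainingConfig,
) -> tuple[AdversaryParams, list[float]]:
    """Step (ii): train the adversary on frozen embeddings."""
    if len(labels.classes) < 2:
        raise ValueError("adversarial training needs >= 2 confounder classes")
    Z = encode(params, data)
    adv = init_adversary(cfg, labels.classes)
    rng = np.random.default_rng(cfg.seed + 3)
    history: list[float] = []
    Y = labels.one_hot()
    for _ in range(cfg.adv_pretrain_epochs):
        for idx in _batches(len(Z), cfg.batch_size, rng):
            _train_adv_batch(adv, Z[idx], Y[idx], cfg.adv_learning_rate, cfg.adv_weight_decay)
        loss = adversary_loss(adv, Z, labels)
        _check_finite(loss, "adversary loss")
        history.append(loss)
    return adv, history


def _train_adv_batch(
    adv: AdversaryParams, zb: np.ndarray, yb: np.ndarray, lr: float, wd: float = 0.0
):
    logits = adv.net.forward(zb, cache=True)
    d_logits = (_softmax(logits) - yb) / len(zb)
    _, dW, db = adv.net.backward(d_logits)
    adv.net.adam_step(dW, db, lr, weight_decay=wd)


def _capped(
    dz_adv: np.ndarray,
    dz_recon: np.ndarray,
    cap: float,
    ref_norm: float | None = None,
) -> np.ndarray:
    """Rescale the adversarial latent gradient to ``cap`` x a recon-scale norm.

    The scale is the larger of the current batch's reconstruction-gradient
    norm and a fixed reference (the first joint round's mean). Capping keeps
    a strong adversary from swamping reconstruction and collapsing the
    latent space; the reference floor keeps the pressure from dying away as
    reconstruction converges and its gradients shrink.
    """
    na = np.linalg.norm(dz_adv)
    scale = max(np.linalg.norm(dz_recon), ref_norm or 0.0)
    if na > cap * scale and na > 0:
        return dz_adv * (cap * scale / na)
    return dz_adv


def _converged(acc_history: list[float], chance: float, cfg: TrainingConfig) -> bool:
    """Joint-training stop rule: the adversary has held at chance level for
    ``adv_stop_patience`` consecutive rounds (deconfounding achieved)."""
    recent = acc_history[-cfg.adv_stop_patience :]
    return len(recent) == cfg.adv_stop_patience and all(
        a <= chance + cfg.adv_stop_margin for a in recent
    )


def joint_adversarial_train(
    params: EncoderDecoderParams,
    adv: AdversaryParams,
    data: np.ndarray,
    labels: ConfounderLabels,
    cfg: TrainingConfig,
    mix_source: np.ndarray | None = None,
) -> tuple[EncoderDecoderParams, AdversaryParams, dict]:
    """Step (iii): alternate autoencoder and adversary updates.

    Per round, one autoencoder epoch updates encoder and decoder to minimize
    reconstruction while maximizing the frozen adversary's loss, then one
    adversary epoch minimizes its cross-entropy with the autoencoder frozen.

    Maximizing the adversary's cross-entropy directly is unbounded (the
    encoder can inflate latent norms to make the adversary confidently wrong,
    which destroys reconstruction and removes no information), so the
    encoder's adversarial term uses the standard bounded surrogate: the
    cross-entropy of the adversary's prediction against the *uniform*
    distribution over confounder classes, weighted by lambda. Its minimum is
    the same fixed point — an adversary at chance level.
    """
    data = np.asarray(data, dtype=float)
    mix_source = data if mix_source is None else np.asarray(mix_source, dtype=float)
    n, g = data.shape
    X = _standardize(params, data)
    Y = labels.one_hot(adv.classes)
    rng = np.random.default_rng(cfg.seed + 4)
    history = {"reconstruction": [], "adversary": [], "probe": []}
    chance = float(Y.mean(axis=0).max())
    ref_norm = None  # running reference: first-round mean recon-gradient norm
    norms: list[float] = []
    best_acc, best_state = np.inf, None
    for _round in range(cfg.joint_rounds):
        # (a) autoencoder phase, adversary frozen
        for idx in _batches(n, cfg.batch_size, rng):
            xb, yb = X[idx], Y[idx]
            z = params.encoder.forward(xb, cache=True)
            xhat = params.decoder.forward(z, cache=True)
            d_out = 2.0 * (xhat - xb) / (len(idx) * g)
            dz_recon, dWd, dbd = params.decoder.backward(d_out)
            if ref_norm is None:
                norms.append(float(np.linalg.norm(dz_recon)))
            logits = adv.net.forward(z, cache=True)
            uniform = np.full_like(yb, 1.0 / yb.shape[1])
            d_logits = (_softmax(logits) - uniform) / len(idx)
            dz_adv, _, _ = adv.net.backward(d_logits)
            dz = dz_recon + _capped(
                cfg.lambda_ * dz_adv, dz_recon, cfg.adv_grad_cap, ref_norm
            )
            _, dWe, dbe = params.encoder.backward(dz)
            if cfg.mix_weight > 0:
                dWm, dbm, _ = _mixture_grads(params, mix_source[idx], z, cfg, rng)
                dWe = [a + b_ for a, b_ in zip(dWe, dWm)]
                dbe = [a + b_ for a, b_ in zip(dbe, dbm)]
            params.decoder.adam_step(dWd, dbd, cfg.learning_rate)
            params.encoder.adam_step(dWe, dbe, cfg.learning_rate)
        # (b) adversary phase, autoencoder frozen
        Z = params.encoder.forward(X)
        for _e in range(cfg.adv_epochs_per_round):
            for idx in _batches(n, cfg.batch_size, rng):
                _train_adv_batch(adv, Z[idx], Y[idx], cfg.adv_learning_rate, cfg.adv_weight_decay)
        rec = reconstruction_loss(params, data)
        ce = adversary_loss(adv, Z, labels)
        _check_finite(rec, "reconstruction loss")
        _check_finite(ce, "adversary loss")
        history["reconstruction"].append(rec)
        history["adversary"].append(ce)
        if ref_norm is None:
            ref_norm = float(np.mean(norms))
        if cfg.adv_stop_margin is not None:
            acc = adversary_accuracy(adv, Z, labels)
            history["probe"].append(acc)
            if acc < best_acc:
                best_acc = acc
                best_state = (
                    params.encoder.get_weights(),
                    params.decoder.get_weights(),
                    adv.net.get_weights(),
                    _round,
                )
            if _round + 1 >= cfg.min_joint_rounds and _converged(
                history["probe"], chance, cfg
            ):
                break
    # the minimax oscillates; return the round where the adversary was most
    # confused rather than whatever state the last round happened to leave
    if best_state is not None and best_acc < history["probe"][-1]:
        enc_w, dec_w, adv_w, best_round = best_state
        params.encoder.set_weights(enc_w)
        params.decoder.set_weights(dec_w)
        adv.net.set_weights(adv_w)
        history["restored_round"] = best_round
    return params, adv, history


def train_adversarial_autoencoder(
    data: np.ndarray,
    labels: ConfounderLabels | list[ConfounderLabels],
    cfg: TrainingConfig,
    gene_ids=None,
    mix_source: np.ndarray | None = None,
) -> tuple[EncoderDecoderParams, AdversaryParams | list[AdversaryParams], dict]:
    """Full three-step schedule on cells x panel-genes data.

    Multiple confounders are handled with one adversary each, their
    cross-entropies summed with equal weight inside the lambda term.
    """
    single = isinstance(labels, ConfounderLabels)
    label_list = [labels] if single else list(labels)
    params, ae_hist = pretrain_autoencoder(data, cfg, gene_ids=gene_ids, mix_source=mix_source)
    advs, adv_hists = [], []
    for lab in label_list:
        a, h = pretrain_adversary(params, data, lab, cfg)
        advs.append(a)
        adv_hists.append(h)
    if len(label_list) == 1:
        params, adv, joint_hist = joint_adversarial_train(
            params, advs[0], data, label_list[0], cfg, mix_source=mix_source
        )
        advs = [adv]
    else:
        params, advs, joint_hist = _joint_multi(
            params, advs, data, label_list, cfg, mix_source=mix_source
        )
    history = {
        "ae_pretrain": ae_hist,
        "adv_pretrain": adv_hists if not single else adv_hists[0],
        "joint": joint_hist,
    }
    return params, (advs[0] if single else advs), history


def _joint_multi(params, advs, data, labels, cfg, mix_source=None):
    """Alternating training with several adversaries (equal-weight sum)."""
    data = np.asarray(data, dtype=float)
    mix_source = data if mix_source is None else np.asarray(mix_source, dtype=float)
    n, g = data.shape
    X = _standardize(params, data)
    Ys = [lab.one_hot(adv.classes) for lab, adv in zip(labels, advs)]
    rng = np.random.default_rng(cfg.seed + 4)
    history = {"reconstruction": [], "adversary": [], "probe": []}
    chances = [float(Y.mean(axis=0).max()) for Y in Ys]
    ref_norm = None
    norms: list[float] = []
    best_acc, best_state = np.inf, None
    for _round in range(cfg.joint_rounds):
        for idx in _batches(n, cfg.batch_size, rng):
            xb = X[idx]
            z = params.encoder.forward(xb, cache=True)
            xhat = params.decoder.forward(z, cache=True)
            d_out = 2.0 * (xhat - xb) / (len(idx) * g)
            dz, dWd, dbd = params.decoder.backward(d_out)
            dz_recon = dz
            if ref_norm is None:
                norms.append(float(np.linalg.norm(dz_recon)))
            for adv, Y in zip(advs, Ys):
                logits = adv.net.forward(z, cache=True)
                uniform = np.full((len(idx), Y.shape[1]), 1.0 / Y.shape[1])
                d_logits = (_softmax(logits) - uniform) / len(idx)
                dz_adv, _, _ = adv.net.backward(d_logits)
                dz = dz + _capped(
                    cfg.lambda_ * dz_adv, dz_recon, cfg.adv_grad_cap, ref_norm
                )
            _, dWe, dbe = params.encoder.backward(dz)
            if cfg.mix_weight > 0:
                dWm, dbm, _ = _mixture_grads(params, mix_source[idx], z, cfg, rng)
                dWe = [a + b_ for a, b_ in zip(dWe, dWm)]
                dbe = [a + b_ for a, b_ in zip(dbe, dbm)]
            params.decoder.adam_step(dWd, dbd, cfg.learning_rate)
            params.encoder.adam_step(dWe, dbe, cfg.learning_rate)
        Z = params.encoder.forward(X)
        for adv, Y in zip(advs, Ys):
            for _e in range(cfg.adv_epochs_per_round):
                for idx in _batches(n, cfg.batch_size, rng):
                    _train_adv_batch(adv, Z[idx], Y[idx], cfg.adv_learning_rate, cfg.adv_weight_decay)
        rec = reconstruction_loss(params, data)
        _check_finite(rec, "reconstruction loss")
        history["reconstruction"].append(rec)
        history["adversary"].append(
            [adversary_loss(a, Z, lab) for a, lab in zip(advs, labels)]
        )
        if ref_norm is None:
            ref_norm = float(np.mean(norms))
        if cfg.adv_stop_margin is not None:
            accs = [adversary_accuracy(a, Z, lab) for a, lab in zip(advs, labels)]
            history["probe"].append(accs)
            if float(np.mean(accs)) < best_acc:
                best_acc = float(np.mean(accs))
                best_state = (
                    params.encoder.get_weights(),
                    params.decoder.get_weights(),
                    [a.net.get_weights() for a in advs],
                    _round,
                )
            per_adv = list(zip(*history["probe"]))
            if _round + 1 >= cfg.min_joint_rounds and all(
                _converged(list(h), c, cfg) for h, c in zip(per_adv, chances)
            ):
                break
    if best_state is not None and best_acc < float(np.mean(history["probe"][-1])):
        enc_w, dec_w, adv_ws, best_round = best_state
        params.encoder.set_weights(enc_w)
        params.decoder.set_weights(dec_w)
        for a, w in zip(advs, adv_ws):
            a.net.set_weights(w)
        history["restored_round"] = best_round
    return params, advs, history


# ---------------------------------------------------------------------------
# evaluation probe
# ---------------------------------------------------------------------------


def probe_accuracy(
    latents: np.ndarray, labels: np.ndarray, seed: int = 0, test_fraction: float = 0.3
) -> float:
    """Held-out accuracy of a fresh linear probe on an embedding.

    Used to measure how decodable a label (batch or cell type) remains from
    trained latents, independently of the adversary's own weights.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels).astype(str)
    Xtr, Xte, ytr, yte = train_test_split(
        latents, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    clf = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
    return float(clf.score(Xte, yte))
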