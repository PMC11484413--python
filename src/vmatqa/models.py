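"""Autoencoder models for per-CP intensity maps.

The principal model is a multi-task autoencoder: a convolutional encoder
maps the (normalized) intensity map of a control point to a latent vector
``h``; one decoder reconstructs the binary aperture map (binary
cross-entropy loss ``L_A``), a second reconstructs the scalar per-CP dose
(mean-square error ``L_D``).  The training objective is the weighted sum
``L_R = lambda * L_A + L_D``, minimized with Adam at learning rate 1e-3.

Architecture (all models share the encoder topology): four down-conv blocks
(3x3 stride-2 conv then 3x3 stride-1 conv, each followed by batch norm and
ReLU) halve the spatial size four times; a linear block (linear + ReLU)
produces ``h``.  The aperture decoder mirrors this with a linear block and
four up-conv blocks (2x2 stride-2 up-convolution then 3x3 stride-1 conv,
each with batch norm + ReLU) and a sigmoid output head; the dose decoder is
three linear blocks plus a linear scalar head.

Baselines for comparison reconstruct the intensity map itself under an MSE
loss: a Vanilla AE, a Contractive AE (Frobenius-norm Jacobian penalty of
the latent w.r.t. the input), and a Variational AE (the latent head emits
(mu, log sigma^2); the KL term against N(0, I) uses its closed form, with
reparameterized sampling during training).

Doses and input intensities are normalized to [0, 1] by the training-set
maximum dose; the factor is stored with the model and undone when
reconstructions are reported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .feature_map import FeatureTensor
from .nn.layers import _BatchNorm
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Flatten,
    Linear,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
    UpConv2d,
)

__all__ = [
    "MODEL_KINDS",
    "ModelConfig",
    "Reconstruction",
    "TrainReport",
    "build_model",
    "loss_aperture",
    "loss_dose",
    "loss_total",
    "kl_divergence",
    "contractive_penalty",
    "regularizer",
    "train",
    "reconstruct",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("multitask", "vanilla", "contractive", "variational")
_EPS = 1e-7


@dataclass
class ModelConfig:
    model_kind: str = "multitask"
    input_shape: Tuple[int, int] = (64, 64)
    latent_dim: int = 32
    channels: Tuple[int, int, int, int] = (8, 16, 32, 64)
    lambda_weight: float = 1.0
    contractive_gamma: float = 1e-4
    vae_beta: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 5
    batch_size: int = 128
    cp_stride: int = 1  # train on every n-th CP (adjacent CPs are near-duplicates)
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        m, n = self.input_shape
        if m % 16 or n % 16:
            raise ValueError(
                f"input shape {self.input_shape} must be divisible by 16 "
                "(four stride-2 halvings)"
            )
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if min(self.lambda_weight, self.contractive_gamma, self.vae_beta) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.cp_stride < 1:
            raise ValueError("cp_stride must be >= 1")


@dataclass
class Reconstruction:
    """Per-CP model outputs for one plan.

    ``aperture_prob`` and ``dose_hat`` are populated by the multi-task
    model (the intensity is assembled as I' = D' * A'); the single-decoder
    baselines populate ``intensity_hat`` directly.
    """

    intensity_hat: np.ndarray  # (K, M, N), physical dose scale
    aperture_prob: Optional[np.ndarray] = None  # (K, M, N) in (0, 1)
    dose_hat: Optional[np.ndarray] = None  # (K,), physical dose scale


@dataclass
class TrainReport:
    losses: dict  # name -> list of per-epoch means
    baseline: dict  # name -> pre-training loss
    checksum: str
    seed: int


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def loss_aperture(a: np.ndarray, a_prob: np.ndarray, eps: float = _EPS) -> float:
    """Mean binary cross-entropy between a binary stack and probabilities."""
    if a.shape != a_prob.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {a_prob.shape}")
    p = np.clip(a_prob.astype(np.float64), eps, 1.0 - eps)
    a = a.astype(np.float64)
    return float(-np.mean(a * np.log(p) + (1.0 - a) * np.log(1.0 - p)))


def loss_dose(d: np.ndarray, d_hat: np.ndarray) -> float:
    """Mean-square error over control points."""
    d = np.asarray(d, dtype=np.float64)
    d_hat = np.asarray(d_hat, dtype=np.float64)
    if d.shape != d_hat.shape:
        raise ValueError(f"length mismatch: {d.shape} vs {d_hat.shape}")
    return float(np.mean((d - d_hat) ** 2))


def loss_total(l_a: float, l_d: float, lambda_weight: float) -> float:
    return lambda_weight * l_a + l_d


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(N(mu, sigma^2) || N(0, 1)), summed over latent, mean over batch."""
    kl = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=-1)
    return float(np.mean(kl))


# ---------------------------------------------------------------------------
# Model definitions
# ---------------------------------------------------------------------------

def _down_block(c_in, c_out, rng):
    return [
        Conv2d(c_in, c_out, stride=2, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
        Conv2d(c_out, c_out, stride=1, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
    ]


def _up_block(c_in, c_out, rng):
    return [
        UpConv2d(c_in, c_out, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
        Conv2d(c_out, c_out, stride=1, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
    ]


class _BaseAE:
    """Shared encoder backbone + bookkeeping."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.dose_norm: float = 1.0
        m, n = config.input_shape
        c = config.channels
        self.spatial = (m // 16, n // 16)
        self.feat_dim = c[3] * self.spatial[0] * self.spatial[1]
        layers = _down_block(1, c[0], self.rng)
        for i in range(3):
            layers += _down_block(c[i], c[i + 1], self.rng)
        layers.append(Flatten())
        self.backbone = Sequential(layers)

    def _image_decoder(self, out_sigmoid: bool) -> Sequential:
        c = self.config.channels
        layers = [
            Linear(self.config.latent_dim, self.feat_dim, self.rng),
            ReLU(),
            Reshape(self.spatial + (c[3],)),
        ]
        layers += _up_block(c[3], c[2], self.rng)
        layers += _up_block(c[2], c[1], self.rng)
        layers += _up_block(c[1], c[0], self.rng)
        layers += _up_block(c[0], c[0], self.rng)
        layers.append(Conv2d(c[0], 1, stride=1, rng=self.rng))
        if out_sigmoid:
            layers.append(Sigmoid())
        return Sequential(layers)

    def modules(self) -> List[Sequential]:
        raise NotImplementedError

    def parameters(self):
        return [p for mod in self.modules() for p in mod.params()]

    def state_arrays(self) -> List[np.ndarray]:
        """All weights and batch-norm running statistics, in fixed order."""
        out = []
        for mod in self.modules():
            for layer in mod.layers:
                out.extend(p.data for p in layer.params())
                if isinstance(layer, _BatchNorm):
                    out.append(layer.running_mean)
                    out.append(layer.running_var)
        return out

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for mod in self.modules():
            for layer in mod.layers:
                for p in layer.params():
                    p.data = next(it).astype(np.float32).reshape(p.data.shape)
                    p.grad = np.zeros_like(p.data)
                if isinstance(layer, _BatchNorm):
                    layer.running_mean = next(it).astype(np.float32)
                    layer.running_var = next(it).astype(np.float32)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(np.ascontiguousarray(a, dtype=np.float32).tobytes())
        return h.hexdigest()

    def encode(self, x: np.ndarray, train: bool = False):
        """Latent vector h for a (B, 1, M, N) batch (eval mode by default)."""
        raise NotImplementedError


class MultiTaskAE(_BaseAE):
    kind = "multitask"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        self.encoder = Sequential(
            self.backbone.layers
            + [Linear(self.feat_dim, config.latent_dim, self.rng), ReLU()]
        )
        self.decoder_aperture = self._image_decoder(out_sigmoid=False)  # logits
        self.decoder_dose = Sequential(
            [
                Linear(config.latent_dim, 64, self.rng),
                ReLU(),
                Linear(64, 32, self.rng),
                ReLU(),
                Linear(32, 16, self.rng),
                ReLU(),
                Linear(16, 1, self.rng),
            ]
        )

    def modules(self):
        return [self.encoder, self.decoder_aperture, self.decoder_dose]

    def calibrate_init(self, x: np.ndarray) -> None:
        h = _calibrate_pre_relu(self.encoder, x)
        _calibrate_pre_relu(self.decoder_aperture, h)
        _calibrate_pre_relu(self.decoder_dose, h)

    def encode(self, x, train=False):
        h, _ = self.encoder.forward(x, train=train, update_stats=False)
        return h


class VanillaAE(_BaseAE):
    kind = "vanilla"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        self.encoder = Sequential(
            self.backbone.layers
            + [Linear(self.feat_dim, config.latent_dim, self.rng), ReLU()]
        )
        self.decoder = self._image_decoder(out_sigmoid=True)

    def modules(self):
        return [self.encoder, self.decoder]

    def calibrate_init(self, x: np.ndarray) -> None:
        h = _calibrate_pre_relu(self.encoder, x)
        _calibrate_pre_relu(self.decoder, h)

    def encode(self, x, train=False):
        h, _ = self.encoder.forward(x, train=train, update_stats=False)
        return h


class ContractiveAE(VanillaAE):
    kind = "contractive"


class VariationalAE(_BaseAE):
    kind = "variational"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        # The latent head is a plain linear layer emitting (mu, log sigma^2);
        # a ReLU here would clamp the log-variance, so the linear block
        # convention is relaxed for the probabilistic head.
        self.stats_head = Sequential(
            [Linear(self.feat_dim, 2 * config.latent_dim, self.rng)]
        )
        self.decoder = self._image_decoder(out_sigmoid=True)

    def modules(self):
        return [self.backbone, self.stats_head, self.decoder]

    def calibrate_init(self, x: np.ndarray) -> None:
        mu, _ = self.encode_stats(x, train=True)
        _calibrate_pre_relu(self.decoder, mu)

    def encode_stats(self, x, train=False):
        f, _ = self.backbone.forward(x, train=train, update_stats=False)
        s, _ = self.stats_head.forward(f, train=train, update_stats=False)
        L = self.config.latent_dim
        return s[:, :L], s[:, L:]

    def encode(self, x, train=False):
        mu, _ = self.encode_stats(x, train=train)
        return mu



def _calibrate_pre_relu(seq: Sequential, x: np.ndarray, q: float = 0.25,
                        margin: float = 0.1) -> np.ndarray:
    """Data-dependent bias initialization for pre-ReLU linear layers.

    The inputs to the fully connected layers are post-ReLU feature vectors,
    which are non-negative and strongly correlated across samples, so at a
    random initialization a unit's pre-activation often has a constant sign
    over the whole dataset - and a unit that starts negative everywhere is
    permanently dead.  Shifting each bias so the q-quantile of the unit's
    pre-activation on a probe batch sits at +margin guarantees most units
    start alive, for every seed (in the spirit of LSUV initialization).
    Returns the probe batch's output so calibration can cascade.
    """
    layers = seq.layers
    for j, layer in enumerate(layers):
        if (
            isinstance(layer, Linear)
            and j + 1 < len(layers)
            and isinstance(layers[j + 1], ReLU)
        ):
            z, _ = layer.forward(x, train=True, update_stats=False)
            shift = (np.quantile(z, q, axis=0) - margin).astype(np.float32)
            layer.b.data -= shift
            x = z - shift
        else:
            x, _ = layer.forward(x, train=True, update_stats=False)
    return x


def build_model(config: ModelConfig):
    cls = {
        "multitask": MultiTaskAE,
        "vanilla": VanillaAE,
        "contractive": ContractiveAE,
        "variational": VariationalAE,
    }[config.model_kind]
    return cls(config)


# ---------------------------------------------------------------------------
# Regularizers
# ---------------------------------------------------------------------------

def contractive_penalty(model, x: np.ndarray) -> float:
    """Exact gamma * mean_b ||dh/dx||_F^2 via one reverse pass per latent unit.

    Batch-norm is evaluated in inference mode so the Jacobian is that of the
    deployed (fixed-statistics) encoder.  Parameter gradients accumulated by
    the reverse passes are discarded.
    """
    if model.kind not in ("contractive", "vanilla"):
        raise ValueError("contractive penalty is defined for the conv-AE encoder")
    h, cache = model.encoder.forward(x, train=False, update_stats=False)
    total = 0.0
    for i in range(h.shape[1]):
        dy = np.zeros_like(h)
        dy[:, i] = 1.0
        dx = model.encoder.backward(dy, cache)
        total += float(np.sum(dx.astype(np.float64) ** 2))
    for p in model.parameters():
        p.zero_grad()
    return model.config.contractive_gamma * total / x.shape[0]


def regularizer(model, batch: np.ndarray) -> float:
    """The model-kind-specific penalty evaluated on a batch.

    contractive: gamma * ||dh/dx||_F^2 (exact, mean over the batch).
    variational: beta * KL(N(mu, sigma^2) || N(0, 1)), closed form.
    """
    kind = model.kind
    if kind == "contractive":
        return contractive_penalty(model, batch)
    if kind == "variational":
        mu, logvar = model.encode_stats(batch, train=False)
        return model.config.vae_beta * kl_divergence(mu, logvar)
    raise ValueError(f"model kind {kind!r} has no regularizer")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))


def _collect_samples(tensors: Sequence[FeatureTensor], stride: int):
    xs = np.concatenate([t.intensities[::1] for t in tensors], axis=0)
    aps = np.concatenate([t.apertures for t in tensors], axis=0)
    ds = np.concatenate([t.doses for t in tensors], axis=0)
    if stride > 1:
        xs, aps, ds = xs[::stride], aps[::stride], ds[::stride]
    return xs, aps, ds


class _Step:
    """One gradient step per model kind; returns the loss terms."""

    def __init__(self, model):
        self.model = model
        self.cfg = model.config
        # Probe size for the contractive finite-difference estimator: small
        # enough to stay within one linear region of the ReLU network, large
        # enough for float32 differences to be well-resolved.
        self.fd_delta = 1e-3

    def __call__(self, xb, ab, db, update: bool, rng):
        kind = self.model.kind
        if kind == "multitask":
            return self._multitask(xb, ab, db, update)
        if kind in ("vanilla", "contractive"):
            return self._intensity(xb, update, rng)
        return self._variational(xb, update, rng)

    def _multitask(self, xb, ab, db, update):
        m = self.model
        lam = self.cfg.lambda_weight
        h, ce = m.encoder.forward(xb, update_stats=update)
        logits, ca = m.decoder_aperture.forward(h, update_stats=update)
        dhat, cd = m.decoder_dose.forward(h, update_stats=update)
        p = _sigmoid(logits[..., 0])
        l_a = loss_aperture(ab, p)
        l_d = loss_dose(db, dhat[:, 0])
        terms = {"L_A": l_a, "L_D": l_d, "L_R": loss_total(l_a, l_d, lam)}
        if update:
            b = xb.shape[0]
            dlogits = (lam * (p - ab) / p[0].size / b).astype(np.float32)[..., None]
            ddhat = (2.0 * (dhat[:, 0] - db) / b).astype(np.float32)[:, None]
            dh = m.decoder_aperture.backward(dlogits, ca)
            dh = dh + m.decoder_dose.backward(ddhat, cd)
            m.encoder.backward(dh, ce, need_input_grad=False)
        return terms

    def _intensity(self, xb, update, rng):
        m = self.model
        h, ce = m.encoder.forward(xb, update_stats=update)
        xhat, cdec = m.decoder.forward(h, update_stats=update)
        mse = loss_dose(xb[..., 0], xhat[..., 0])
        terms = {"L_I": mse}
        b = xb.shape[0]
        dh_pen = None
        if m.kind == "contractive" and self.cfg.contractive_gamma > 0:
            # Hutchinson finite-difference estimate of the Jacobian norm:
            # E_eps ||(h(x + d*eps) - h(x)) / d||^2 -> ||dh/dx||_F^2.
            eps = rng.standard_normal(xb.shape).astype(np.float32)
            h2, ce2 = m.encoder.forward(
                xb + self.fd_delta * eps, update_stats=False
            )
            diff = (h2 - h) / self.fd_delta
            pen = float(np.mean(np.sum(diff.astype(np.float64) ** 2, axis=1)))
            terms["contractive"] = self.cfg.contractive_gamma * pen
            if update:
                scale = 2.0 * self.cfg.contractive_gamma / (self.fd_delta**2 * b)
                dh_pen = (scale * (h - h2)).astype(np.float32)
                m.encoder.backward(-dh_pen, ce2, need_input_grad=False)
        terms["L_R"] = sum(terms.values())
        if update:
            dxhat = (2.0 * (xhat - xb) / (b * xb[0].size)).astype(np.float32)
            dh = m.decoder.backward(dxhat, cdec)
            if dh_pen is not None:
                dh = dh + dh_pen
            m.encoder.backward(dh, ce, need_input_grad=False)
        return terms

    def _variational(self, xb, update, rng):
        m = self.model
        cfg = self.cfg
        L = cfg.latent_dim
        b = xb.shape[0]
        f, cb = m.backbone.forward(xb, update_stats=update)
        s, ch = m.stats_head.forward(f, update_stats=update)
        mu, logvar = s[:, :L], s[:, L:]
        std = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        z = mu + std * eps
        xhat, cdec = m.decoder.forward(z, update_stats=update)
        mse = loss_dose(xb[..., 0], xhat[..., 0])
        kl = kl_divergence(mu, logvar)
        # KL is normalized per pixel so both terms are per-pixel rates.
        beta_eff = cfg.vae_beta / xb[0].size
        terms = {"L_I": mse, "KL": kl, "L_R": mse + beta_eff * kl}
        if update:
            dxhat = (2.0 * (xhat - xb) / (b * xb[0].size)).astype(np.float32)
            dz = m.decoder.backward(dxhat, cdec)
            dmu = dz + (beta_eff / b) * mu
            dlogvar = dz * eps * std * 0.5 - (beta_eff / b) * 0.5 * (
                1.0 - np.exp(logvar)
            )
            ds = np.concatenate([dmu, dlogvar], axis=1).astype(np.float32)
            df = m.stats_head.backward(ds, ch)
            m.backbone.backward(df, cb, need_input_grad=False)
        return terms


def train(
    model,
    tensors: Sequence[FeatureTensor],
    config: Optional[ModelConfig] = None,
) -> TrainReport:
    """Fit a model on the CP samples of a (regular-only) training set.

    The training unit is the individual control point: each minibatch is a
    set of intensity maps, with targets chosen by the model kind.  Doses
    and input maps are normalized by the training-set maximum dose; the
    factor is stored on the model.  Fully seeded and single-CPU
    reproducible.
    """
    cfg = config or model.config
    if not tensors:
        raise ValueError("empty training set")
    if any(t.label == "anomalous" for t in tensors):
        raise ValueError("training set must contain regular plans only")

    xs, aps, ds = _collect_samples(tensors, cfg.cp_stride)
    max_dose = float(max(float(t.doses.max()) for t in tensors))
    model.dose_norm = max_dose if max_dose > 0 else 1.0
    x = (xs / model.dose_norm).astype(np.float32)[..., None]
    a = aps.astype(np.float32)
    d = (ds / model.dose_norm).astype(np.float32)
    n = x.shape[0]

    if cfg.epochs > 0:
        # deterministic probe batch; shifts pre-ReLU biases so every seed
        # starts with live units (see _calibrate_pre_relu)
        model.calibrate_init(x[: min(256, n)])

    step = _Step(model)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0FFEE]))

    def run_epoch(update: bool):
        order = rng.permutation(n) if update else np.arange(n)
        sums, count = {}, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            if update:
                opt.zero_grad()
            terms = step(x[idx], a[idx], d[idx], update, rng)
            if not all(np.isfinite(v) for v in terms.values()):
                raise RuntimeError(
                    f"non-finite loss {terms} while training {model.kind}"
                )
            if update:
                opt.step()
            for k, v in terms.items():
                sums[k] = sums.get(k, 0.0) + v * len(idx)
            count += len(idx)
        return {k: v / count for k, v in sums.items()}

    baseline = run_epoch(update=False)
    losses: dict = {k: [] for k in baseline}
    for _ in range(cfg.epochs):
        epoch_means = run_epoch(update=True)
        for k, v in epoch_means.items():
            losses.setdefault(k, []).append(v)

    return TrainReport(
        losses=losses, baseline=baseline, checksum=model.checksum(), seed=cfg.seed
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def reconstruct(model, tensor: FeatureTensor, chunk: int = 256) -> Reconstruction:
    """Run a trained model over every CP of a plan (inference mode).

    The multi-task model returns aperture probabilities A' (strictly inside
    (0, 1)), denormalized doses D', and the assembled intensity
    I' = D' * A'; the baselines return the reconstructed intensity directly.
    The variational model uses the latent mean (no sampling) at inference.
    """
    if tensor.map_shape != tuple(model.config.input_shape):
        raise ValueError(
            f"tensor maps {tensor.map_shape} do not match the model input "
            f"shape {tuple(model.config.input_shape)}"
        )
    x_all = (tensor.intensities / model.dose_norm).astype(np.float32)[..., None]
    k_total = x_all.shape[0]
    probs, doses, intens = [], [], []
    for lo in range(0, k_total, chunk):
        xb = x_all[lo : lo + chunk]
        if model.kind == "multitask":
            h, _ = model.encoder.forward(xb, train=False, update_stats=False)
            logits, _ = model.decoder_aperture.forward(
                h, train=False, update_stats=False
            )
            dhat, _ = model.decoder_dose.forward(h, train=False, update_stats=False)
            p = np.clip(_sigmoid(logits[..., 0]), _EPS, 1.0 - _EPS)
            d_phys = dhat[:, 0].astype(np.float64) * model.dose_norm
            probs.append(p)
            doses.append(d_phys)
            intens.append(d_phys[:, None, None] * p)
        elif model.kind == "variational":
            mu, _ = model.encode_stats(xb, train=False)
            xhat, _ = model.decoder.forward(mu, train=False, update_stats=False)
            intens.append(xhat[..., 0].astype(np.float64) * model.dose_norm)
        else:
            h, _ = model.encoder.forward(xb, train=False, update_stats=False)
            xhat, _ = model.decoder.forward(h, train=False, update_stats=False)
            intens.append(xhat[..., 0].astype(np.float64) * model.dose_norm)
    if model.kind == "multitask":
        return Reconstruction(
            intensity_hat=np.concatenate(intens),
            aperture_prob=np.concatenate(probs),
            dose_hat=np.concatenate(doses),
        )
    return Reconstruction(intensity_hat=np.concatenate(intens))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Single-file checkpoint: weights + config + dose normalization."""
    meta = {
        "config": asdict(model.config),
        "dose_norm": model.dose_norm,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_model(path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    cfg_d = meta["config"]
    cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg = ModelConfig(**cfg_d)
    model = build_model(cfg)
    model.load_state_arrays(arrays)
    model.dose_norm = float(meta["dose_norm"])
    return model
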