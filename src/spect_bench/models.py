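"""The four 3D patch-denoising architectures and their training loop.

All four map a noisy ``s^3`` single-channel patch to a denoised patch:

* ``CNN`` - 8 convolutional layers (8 filters, 3x3x3, ReLU) with additive
  skip connections between consecutive layers, a 1-channel projection
  convolution and a global input-to-output residual.
* ``RES`` - the CNN with its convolution blocks replaced by residual units
  (conv-ReLU-conv plus identity, ReLU after the addition).
* ``UNET`` - encoder/decoder with two 3x3x3 conv+ReLU per resolution level,
  2x max pooling down, transposed-convolution up, skip concatenation.
* ``CGAN`` - a UNET-shaped generator trained adversarially against a
  conditional discriminator (4 strided 4x4x4 conv + LeakyReLU layers and a
  fully connected sigmoid unit) that sees the candidate patch concatenated
  with its noisy input.

CNN/RES/UNET minimize the L2 norm; the cGAN generator minimizes
``L2 + lambda * BCE(D(G(x)), real)`` while the discriminator minimizes the
usual binary cross-entropy.  Training uses Adam at default settings, is
fully seeded, and records per-epoch loss histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,
    Conv3d,
    ConvTranspose3d,
    Dense,
    LeakyReLU,
    MaxPool3d,
    ReLU,
    bce_with_logits,
    mse_loss,
    sigmoid,
)
from .nn.layers import F32, Layer
from .patches import PatchSet, crop_patches, recombine_patches
from .volume import Volume

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "denoise_volume",
    "MODEL_KINDS",
]

MODEL_KINDS = ("CNN", "RES", "UNET", "CGAN")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters.

    ``patch_size``/``infer_stride`` control whole-volume inference tiling;
    UNET/CGAN require the patch size divisible by ``2**(levels-1)`` (and by
    16 for the CGAN discriminator's four stride-2 layers).
    """

    kind: str = "CNN"
    n_layers: int = 8
    n_filters: int = 8
    kernel: int = 3
    levels: int = 3
    lambda_adv: float = 0.01
    patch_size: int = 32
    infer_stride: int = 8

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {MODEL_KINDS}")
        if self.n_filters < 1 or self.n_layers < 1:
            raise ValueError("layers and filters must be >= 1")
        if self.lambda_adv < 0:
            raise ValueError("adversarial weight must be >= 0")
        if self.kind in ("UNET", "CGAN") and self.patch_size % 2 ** (self.levels - 1):
            raise ValueError("patch size must be divisible by 2**(levels-1)")
        if self.kind == "CGAN" and self.patch_size % 16:
            raise ValueError("CGAN discriminator needs patch size divisible by 16")


@dataclass(frozen=True)
class TrainConfig:
    """Training budget; defaults mirror the full-scale protocol."""

    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")


class _Sequentialish:
    """Shared plumbing: ordered layer list for optimizers and (de)serialization."""

    layers: list[Layer]

    def parameters(self) -> list[Layer]:
        return [l for l in self.layers if l.params]


class _CNN(_Sequentialish):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        f, k = spec.n_filters, spec.kernel
        self.convs = [Conv3d(1, f, k, rng=rng)]
        self.convs += [Conv3d(f, f, k, rng=rng) for _ in range(spec.n_layers - 1)]
        self.relus = [ReLU() for _ in range(spec.n_layers)]
        self.proj = Conv3d(f, 1, k, rng=rng, init_scale=0.1)
        self.layers = [*self.convs, self.proj]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relus[0].forward(self.convs[0].forward(x))
        for conv, relu in zip(self.convs[1:], self.relus[1:]):
            h = h + relu.forward(conv.forward(h))
        return x + self.proj.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.proj.backward(dout)
        for conv, relu in zip(reversed(self.convs[1:]), reversed(self.relus[1:])):
            dh = dh + conv.backward(relu.backward(dh))
        dx = self.convs[0].backward(self.relus[0].backward(dh))
        return dx + dout


class _RES(_Sequentialish):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        f, k = spec.n_filters, spec.kernel
        n_units = max(1, spec.n_layers // 2)
        self.stem = Conv3d(1, f, k, rng=rng)
        self.stem_relu = ReLU()
        self.units = [
            (Conv3d(f, f, k, rng=rng), ReLU(), Conv3d(f, f, k, rng=rng), ReLU())
            for _ in range(n_units)
        ]
        self.proj = Conv3d(f, 1, k, rng=rng, init_scale=0.1)
        self.layers = [self.stem] + [
            l for c1, _, c2, _ in self.units for l in (c1, c2)
        ] + [self.proj]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.stem_relu.forward(self.stem.forward(x))
        for c1, r1, c2, r_post in self.units:
            t = c2.forward(r1.forward(c1.forward(h)))
            h = r_post.forward(h + t)
        return x + self.proj.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.proj.backward(dout)
        for c1, r1, c2, r_post in reversed(self.units):
            da = r_post.backward(dh)
            dh = da + c1.backward(r1.backward(c2.backward(da)))
        dx = self.stem.backward(self.stem_relu.backward(dh))
        return dx + dout


class _UNet(_Sequentialish):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        f0, k, levels = spec.n_filters, spec.kernel, spec.levels
        filt = [f0 * 2**i for i in range(levels)]
        self.levels = levels
        self.enc = []
        c_in = 1
        for f in filt:
            self.enc.append(
                (Conv3d(c_in, f, k, rng=rng), ReLU(), Conv3d(f, f, k, rng=rng), ReLU())
            )
            c_in = f
        self.pools = [MaxPool3d() for _ in range(levels - 1)]
        self.ups = []
        self.dec = []
        for i in range(levels - 2, -1, -1):
            self.ups.append(ConvTranspose3d(filt[i + 1], filt[i], rng=rng))
            self.dec.append(
                (
                    Conv3d(2 * filt[i], filt[i], k, rng=rng), ReLU(),
                    Conv3d(filt[i], filt[i], k, rng=rng), ReLU(),
                )
            )
        self.proj = Conv3d(filt[0], 1, k, rng=rng, init_scale=0.1)
        self.layers = (
            [l for c1, _, c2, _ in self.enc for l in (c1, c2)]
            + self.ups
            + [l for c1, _, c2, _ in self.dec for l in (c1, c2)]
            + [self.proj]
        )

    @staticmethod
    def _block(block, x):
        c1, r1, c2, r2 = block
        return r2.forward(c2.forward(r1.forward(c1.forward(x))))

    @staticmethod
    def _block_back(block, dy):
        c1, r1, c2, r2 = block
        return c1.backward(r1.backward(c2.backward(r2.backward(dy))))

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = self._block(block, h)
            if i < self.levels - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=-1)
            h = self._block(block, h)
        return x + self.proj.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.proj.backward(dout)
        # reversed(dec)[j] pairs with skips[j], so dskips lands in skip order
        dskips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec)):
            dcat = self._block_back(block, dh)
            ch = dcat.shape[-1] // 2
            dskips.append(np.ascontiguousarray(dcat[..., :ch]))
            dh = up.backward(np.ascontiguousarray(dcat[..., ch:]))
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                dh = self.pools[i].backward(dh) + dskips[i]
            dh = self._block_back(self.enc[i], dh)
        return dh + dout


class _Discriminator(_Sequentialish):
    """Conditional discriminator: (noisy, candidate) channel pair -> P(real)."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        f = spec.n_filters
        chans = [2, f, 2 * f, 4 * f, 8 * f]
        self.convs = [
            Conv3d(chans[i], chans[i + 1], kernel=4, stride=2, pad=1, rng=rng)
            for i in range(4)
        ]
        self.acts = [LeakyReLU(0.2) for _ in range(4)]
        side = spec.patch_size // 16
        self.fc = Dense(chans[-1] * side**3, 1, rng=rng)
        self.layers = [*self.convs, self.fc]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
        return self.fc.forward(h)  # logits; sigmoid applied in the loss / predict

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        dh = self.fc.backward(dlogit)
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            dh = conv.backward(act.backward(dh))
        return dh

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x))


_GENERATORS = {"CNN": _CNN, "RES": _RES, "UNET": _UNet, "CGAN": _UNet}


@dataclass
class TrainedModel:
    """A (possibly untrained) denoising model plus its training history."""

    spec: ModelSpec
    net: _Sequentialish
    disc: _Discriminator | None = None
    history: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def trained(self) -> bool:
        return len(self.history) > 0

    def save(self, path: str) -> None:
        """Checkpoint: npz weights + JSON spec/history sidecar."""
        arrays = {}
        for i, layer in enumerate(self.net.parameters()):
            for k, v in layer.params.items():
                arrays[f"g{i}_{k}"] = v
        if self.disc is not None:
            for i, layer in enumerate(self.disc.parameters()):
                for k, v in layer.params.items():
                    arrays[f"d{i}_{k}"] = v
        np.savez_compressed(path, **arrays)
        side = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
        with open(side, "w") as f:
            json.dump(
                {"spec": asdict(self.spec), "history": self.history,
                 "meta": self.meta, "seed": self.seed},
                f, indent=1,
            )

    @staticmethod
    def load(path: str) -> "TrainedModel":
        side = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
        with open(side) as f:
            blob = json.load(f)
        model = build_model(ModelSpec(**blob["spec"]), seed=blob["seed"])
        model.history = blob["history"]
        model.meta = blob["meta"]
        with np.load(path) as data:
            for i, layer in enumerate(model.net.parameters()):
                for k in layer.params:
                    layer.params[k] = data[f"g{i}_{k}"]
            if model.disc is not None:
                for i, layer in enumerate(model.disc.parameters()):
                    for k in layer.params:
                        layer.params[k] = data[f"d{i}_{k}"]
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained model with seeded He initialization.

    The generator draws from an RNG stream independent of the
    discriminator's, so a CGAN generator is initialized identically to a
    UNET built from the same seed.
    """
    gen_rng = np.random.default_rng([seed, 101])
    net = _GENERATORS[spec.kind](spec, gen_rng)
    disc = None
    if spec.kind == "CGAN":
        disc = _Discriminator(spec, np.random.default_rng([seed, 202]))
    return TrainedModel(spec=spec, net=net, disc=disc, seed=seed)


def _as_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    noisy, clean = pairs
    x = noisy.patches if isinstance(noisy, PatchSet) else np.asarray(noisy)
    y = clean.patches if isinstance(clean, PatchSet) else np.asarray(clean)
    if len(x) != len(y):
        raise ValueError(f"mismatched pair counts: {len(x)} noisy vs {len(y)} clean")
    if len(x) == 0:
        raise ValueError("empty training set")
    return x[..., None].astype(F32), y[..., None].astype(F32)


def train(model: TrainedModel, pairs, cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Train in place on aligned (noisy, clean) patch pairs; returns the model.

    Seeded and reproducible: the shuffle stream depends only on
    ``cfg.seed``, not on the architecture, so matched seeds see identical
    batch orderings.  A non-finite loss aborts with a diagnostic.
    """
    x, y = _as_xy(pairs)
    rng = np.random.default_rng([cfg.seed, 303])
    n_val = int(round(cfg.val_fraction * len(x)))
    if n_val:
        x, x_val = x[:-n_val], x[-n_val:]
        y, y_val = y[:-n_val], y[-n_val:]
    adversarial = model.spec.kind == "CGAN" and model.disc is not None
    g_opt = Adam(model.net.parameters(), lr=cfg.lr)
    d_opt = Adam(model.disc.parameters(), lr=cfg.lr) if adversarial else None
    lam = model.spec.lambda_adv

    model.meta = {
        "epochs": cfg.epochs, "batch_size": cfg.batch_size,
        "optimizer": "adam", "lr": cfg.lr,
        "betas": [0.9, 0.999], "seed": cfg.seed, "n_pairs": len(x),
    }

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        logs: dict[str, list[float]] = {}
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]

            if adversarial:
                fake = model.net.forward(xb)
                # discriminator pass: real pairs labelled 1, denoised 0
                d_in = np.concatenate(
                    [np.concatenate([xb, yb], axis=-1),
                     np.concatenate([xb, fake], axis=-1)], axis=0
                ).astype(F32)
                labels = np.concatenate(
                    [np.ones((len(xb), 1)), np.zeros((len(xb), 1))]
                )
                d_loss, dlogit = bce_with_logits(model.disc.forward(d_in), labels)
                model.disc.backward(dlogit.astype(F32))
                d_opt.step()
                logs.setdefault("d_loss", []).append(d_loss)

                l2, dfake = mse_loss(fake, yb)
                if lam > 0:
                    g_in = np.concatenate([xb, fake], axis=-1).astype(F32)
                    adv, dlog = bce_with_logits(
                        model.disc.forward(g_in), np.ones((len(xb), 1))
                    )
                    dg = model.disc.backward(dlog.astype(F32))[..., 1:2]
                    dfake = dfake + lam * dg
                else:
                    adv = 0.0
                loss = l2 + lam * adv
                model.net.backward(dfake.astype(F32))
                g_opt.step()
                logs.setdefault("g_l2", []).append(l2)
                logs.setdefault("g_adv", []).append(adv)
                logs.setdefault("loss", []).append(loss)
            else:
                out = model.net.forward(xb)
                loss, dout = mse_loss(out, yb)
                model.net.backward(dout)
                g_opt.step()
                logs.setdefault("loss", []).append(loss)

            if not np.isfinite(logs["loss"][-1]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                    f" (kind={model.spec.kind}); try a lower learning rate"
                )

        entry = {"epoch": epoch}
        entry.update({k: float(np.mean(v)) for k, v in logs.items()})
        if n_val:
            val_out = _predict_batched(model, x_val, cfg.batch_size)
            entry["val_loss"] = float(np.mean((val_out - y_val) ** 2))
        model.history.append(entry)
    return model


def _predict_batched(model: TrainedModel, x: np.ndarray, batch: int) -> np.ndarray:
    outs = [
        model.net.forward(x[i:i + batch]) for i in range(0, len(x), batch)
    ]
    return np.concatenate(outs, axis=0)


def denoise_volume(
    model: TrainedModel, vol: Volume, batch_size: int = 16
) -> Volume:
    """Denoise a whole volume: crop -> per-patch inference -> recombination.

    The volume is normalized by its mean before inference (the scale the
    model was trained at) and rescaled afterwards; output is clipped at 0.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    scale = float(vol.data.mean())
    if scale <= 0:
        scale = 1.0
    ps = crop_patches(vol, model.spec.patch_size, model.spec.infer_stride)
    x = (ps.patches[..., None] / scale).astype(F32)
    out = _predict_batched(model, x, batch_size)
    den = recombine_patches(ps.with_patches(out[..., 0].astype(np.float64) * scale))
    den.data = np.clip(den.data, 0.0, None)
    den.orientation = vol.orientation
    return den
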