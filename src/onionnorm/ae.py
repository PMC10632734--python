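"""1D convolutional autoencoder residual normalization (pure numpy).

Gene profiles (one channel, length = number of cell lines) are passed
through an hourglass network; after training, the decoder output is a
"reconstructed" profile capturing the dominant low-dimensional signal, and
subtracting it from the (preprocessed) input yields the AE-normalized data.

Architecture (kernel size 3, pooling size 2 throughout):

    encoder: conv(1 -> 10) -> maxpool -> conv(10 -> 20) -> maxpool
             -> flatten -> linear(-> LS)
    decoder: linear(LS -> flat) -> unflatten -> max-unpool
             -> transposed conv(20 -> 10) -> max-unpool
             -> transposed conv(10 -> 1) -> linear(T -> T)

Max-unpooling consumes the pooling indices stored during the encoder pass.
With stride 1 and symmetric zero padding, a transposed convolution is the
correlation with the flipped, channel-transposed kernel, i.e. the same
parameterized linear map as a convolution; the decoder convolutions are
implemented that way. Training is mini-batch Adam on mean squared
reconstruction error, fully seeded and therefore bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GeneEffectMatrix, NormalizedLayer, ae_preprocess, impute_gene_mean

#: latent-size grid used for the AE onion (AEO): 6 normalized layers
AE_LATENT_GRID: tuple[int, ...] = (1, 2, 3, 4, 5, 10)


@dataclass
class AeConfig:
    """Hyperparameters of the convolutional autoencoder."""

    latent_size: int = 1
    epochs: int = 1
    conv_channels: tuple[int, int] = (10, 20)
    kernel_size: int = 3
    pool_size: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_size < 1:
            raise ValueError("latent_size must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (symmetric padding)")


# -- primitive layers (forward + backward) ------------------------------------

def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation with symmetric zero padding; x (B,Ci,T) -> (B,Co,T)."""
    k = w.shape[2]
    pad = k // 2
    t = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    y = np.zeros((x.shape[0], w.shape[0], t))
    for dk in range(k):
        y += np.einsum("oi,bit->bot", w[:, :, dk], xp[:, :, dk:dk + t])
    return y + b[None, :, None]


def _conv1d_backward(dy, x, w):
    k = w.shape[2]
    pad = k // 2
    t = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for dk in range(k):
        dw[:, :, dk] = np.einsum("bot,bit->oi", dy, xp[:, :, dk:dk + t])
        dxp[:, :, dk:dk + t] += np.einsum("oi,bot->bit", w[:, :, dk], dy)
    db = dy.sum(axis=(0, 2))
    return dxp[:, :, pad:pad + t], dw, db


def _maxpool(x: np.ndarray, p: int):
    """Non-overlapping max pooling; trailing remainder is dropped."""
    b, c, t = x.shape
    t_out = t // p
    xv = x[:, :, : t_out * p].reshape(b, c, t_out, p)
    idx = xv.argmax(axis=3)
    y = np.take_along_axis(xv, idx[..., None], axis=3)[..., 0]
    return y, idx, t


def _maxunpool(y: np.ndarray, idx: np.ndarray, p: int, t_orig: int) -> np.ndarray:
    b, c, t_out = y.shape
    out = np.zeros((b, c, t_out, p))
    np.put_along_axis(out, idx[..., None], y[..., None], axis=3)
    full = np.zeros((b, c, t_orig))
    full[:, :, : t_out * p] = out.reshape(b, c, t_out * p)
    return full


def _unpool_backward(dfull: np.ndarray, idx: np.ndarray, p: int) -> np.ndarray:
    b, c, t_out = idx.shape
    dv = dfull[:, :, : t_out * p].reshape(b, c, t_out, p)
    return np.take_along_axis(dv, idx[..., None], axis=3)[..., 0]


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict,
             beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * g * g
            mhat = self.m[k] / (1 - beta1**self.t)
            vhat = self.v[k] / (1 - beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class ConvAutoencoder(BaseEstimator, TransformerMixin):
    """Hourglass 1D-convolutional autoencoder over gene profiles.

    ``fit`` expects an array of shape (n_profiles, profile_length) of
    preprocessed values; ``transform`` returns the reconstruction residual
    (input minus decoder output).
    """

    def __init__(self, latent_size: int = 1, epochs: int = 1,
                 conv_channels: tuple[int, int] = (10, 20), kernel_size: int = 3,
                 pool_size: int = 2, learning_rate: float = 1e-3,
                 batch_size: int = 64, seed: int = 0):
        self.latent_size = latent_size
        self.epochs = epochs
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    # -- parameter bookkeeping ------------------------------------------------
    def _init_params(self, t: int, rng: np.random.Generator) -> dict:
        c1, c2 = self.conv_channels
        k, p, ls = self.kernel_size, self.pool_size, self.latent_size
        t1 = t // p
        t2 = t1 // p
        if t2 < 1:
            raise ValueError(f"profile_length={t} too small for two pooling stages")
        self._t, self._t1, self._t2 = t, t1, t2
        flat = c2 * t2

        def u(shape, fan_in):
            s = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-s, s, size=shape)

        return {
            "w1": u((c1, 1, k), k), "b1": u((c1,), k),
            "w2": u((c2, c1, k), c1 * k), "b2": u((c2,), c1 * k),
            "we": u((ls, flat), flat), "be": u((ls,), flat),
            "wd": u((flat, ls), ls), "bd": u((flat,), ls),
            "w3": u((c1, c2, k), c2 * k), "b3": u((c1,), c2 * k),
            "w4": u((1, c1, k), c1 * k), "b4": u((1,), c1 * k),
            "wf": u((t, t), t), "bf": u((t,), t),
        }

    def n_parameters_(self) -> int:
        check_is_fitted(self, "params_")
        return int(sum(v.size for v in self.params_.values()))

    # -- forward / backward ---------------------------------------------------
    def _forward(self, params: dict, x: np.ndarray):
        p = self.pool_size
        c = {"x": x[:, None, :]}
        c["a1"] = _conv1d(c["x"], params["w1"], params["b1"])
        c["p1"], c["i1"], c["t1_in"] = _maxpool(c["a1"], p)
        c["a2"] = _conv1d(c["p1"], params["w2"], params["b2"])
        c["p2"], c["i2"], c["t2_in"] = _maxpool(c["a2"], p)
        b = x.shape[0]
        c["flat"] = c["p2"].reshape(b, -1)
        c["z"] = c["flat"] @ params["we"].T + params["be"]
        c["dflat"] = c["z"] @ params["wd"].T + params["bd"]
        c["dp2"] = c["dflat"].reshape(c["p2"].shape)
        c["u2"] = _maxunpool(c["dp2"], c["i2"], p, c["t2_in"])
        c["a3"] = _conv1d(c["u2"], params["w3"], params["b3"])
        c["u1"] = _maxunpool(c["a3"], c["i1"], p, c["t1_in"])
        c["a4"] = _conv1d(c["u1"], params["w4"], params["b4"])
        c["y"] = c["a4"][:, 0, :] @ params["wf"].T + params["bf"]
        return c

    def _backward(self, params: dict, c: dict, dy: np.ndarray) -> dict:
        p = self.pool_size
        g: dict = {}
        g["wf"] = dy.T @ c["a4"][:, 0, :]
        g["bf"] = dy.sum(axis=0)
        da4 = (dy @ params["wf"])[:, None, :]
        du1, g["w4"], g["b4"] = _conv1d_backward(da4, c["u1"], params["w4"])
        da3 = _unpool_backward(du1, c["i1"], p)
        du2, g["w3"], g["b3"] = _conv1d_backward(da3, c["u2"], params["w3"])
        ddp2 = _unpool_backward(du2, c["i2"], p)
        ddflat = ddp2.reshape(ddp2.shape[0], -1)
        g["wd"] = ddflat.T @ c["z"]
        g["bd"] = ddflat.sum(axis=0)
        dz = ddflat @ params["wd"]
        g["we"] = dz.T @ c["flat"]
        g["be"] = dz.sum(axis=0)
        dflat = dz @ params["we"]
        dp2 = dflat.reshape(c["p2"].shape)
        da2 = _maxunpool(dp2, c["i2"], p, c["t2_in"])
        dp1, g["w2"], g["b2"] = _conv1d_backward(da2, c["p1"], params["w2"])
        da1 = _maxunpool(dp1, c["i1"], p, c["t1_in"])
        _, g["w1"], g["b1"] = _conv1d_backward(da1, c["x"], params["w1"])
        return g

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_profiles, profile_length)")
        n, t = X.shape
        if t < 2 * self.pool_size**2:
            raise ValueError(f"profile_length={t} too small for the pooling chain")
        rng = np.random.default_rng(self.seed)
        params = self._init_params(t, rng)
        opt = _Adam(params, self.learning_rate)
        self.loss_history_ = []
        bs = self.batch_size
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                batch = X[order[start:start + bs]]
                c = self._forward(params, batch)
                err = c["y"] - batch
                loss = float((err**2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at lr={self.learning_rate}, "
                        f"batch starting at {start}"
                    )
                self.loss_history_.append(loss)
                dy = 2.0 * err / err.size
                grads = self._backward(params, c, dy)
                opt.step(params, grads)
        self.params_ = params
        self.profile_length_ = t
        return self

    def reconstruct(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        return self._forward(self.params_, X)["y"]

    def transform(self, X) -> np.ndarray:
        """Residual: input minus reconstruction."""
        return np.asarray(X, dtype=float) - self.reconstruct(X)

    def loss(self, X) -> float:
        """Mean squared reconstruction error on X with current parameters."""
        err = self.reconstruct(X) - np.asarray(X, dtype=float)
        return float((err**2).mean())


def build_autoencoder(profile_length: int, cfg: AeConfig) -> ConvAutoencoder:
    """Construct (and shape-check) an untrained model for a profile length."""
    if profile_length < 2 * cfg.pool_size**2:
        raise ValueError(f"profile_length={profile_length} too small for the pooling chain")
    model = ConvAutoencoder(
        latent_size=cfg.latent_size, epochs=cfg.epochs,
        conv_channels=cfg.conv_channels, kernel_size=cfg.kernel_size,
        pool_size=cfg.pool_size, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    model.params_ = model._init_params(profile_length, rng)
    model.profile_length_ = profile_length
    return model


def ae_normalize(
    mat: GeneEffectMatrix, cfg: AeConfig, preprocess: bool = True,
) -> tuple[NormalizedLayer, NormalizedLayer]:
    """Train the autoencoder on gene profiles and subtract its reconstruction.

    Returns (normalized layer, reconstructed layer). The subtraction base is
    the preprocessed matrix, since the reconstruction lives in the
    preprocessed value space; pass ``preprocess=False`` for data already in
    that space.
    """
    work = mat
    if preprocess:
        work = ae_preprocess(impute_gene_mean(mat))
    X = work.genes_matrix()
    model = ConvAutoencoder(
        latent_size=cfg.latent_size, epochs=cfg.epochs,
        conv_channels=cfg.conv_channels, kernel_size=cfg.kernel_size,
        pool_size=cfg.pool_size, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, seed=cfg.seed,
    ).fit(X)
    recon = model.reconstruct(X)
    src = mat.content_hash()

    def _layer(values, method):
        gm = GeneEffectMatrix(values, work.gene_ids, work.sample_ids,
                              orientation="genes_as_rows",
                              gene_labels=work.gene_labels)
        return NormalizedLayer(matrix=gm.as_orientation(mat.orientation),
                               method=method, hyperparameter=cfg.latent_size,
                               source_hash=src)

    return _layer(X - recon, "ae"), _layer(recon, "ae_reconstructed")
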