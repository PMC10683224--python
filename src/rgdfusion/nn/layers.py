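"""Neural-network layers over the autodiff engine.

Activations are (B, C, D, H, W) volumes.  Convolutions are expressed as an
im2col gather followed by a matmul, so their gradients come for free from the
engine.  Max pooling carries an argmax mask backward.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, relu, sigmoid

__all__ = [
    "Module",
    "Dense",
    "Conv3d",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "relu",
    "sigmoid",
    "concat",
]


class Module:
    """Base class; subclasses register Tensor parameters as attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float32).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return Tensor(w.astype(np.float32), requires_grad=True)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _he_init(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv3d(Module):
    """3D convolution with per-axis kernel/stride/padding via im2col.

    Planar (2D) convolutions are the special case kernel depth 1.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
        stride: tuple[int, int, int] = (1, 1, 1),
        padding: tuple[int, int, int] = (0, 0, 0),
    ):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        k = int(np.prod(kernel)) * c_in
        self.w = _he_init(rng, (k, c_out), k)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self._index_cache: dict[tuple[int, int, int], tuple] = {}

    def _indices(self, D: int, H: int, W: int):
        key = (D, H, W)
        if key in self._index_cache:
            return self._index_cache[key]
        # D, H, W are the *already padded* input dims
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        Dp, Hp, Wp = D, H, W
        od = (Dp - kd) // sd + 1
        oh = (Hp - kh) // sh + 1
        ow = (Wp - kw) // sw + 1
        # flat index into padded (C, Dp, Hp, Wp) for every (out position, tap)
        zo = np.arange(od) * sd
        yo = np.arange(oh) * sh
        xo = np.arange(ow) * sw
        kz, ky, kx = np.meshgrid(
            np.arange(kd), np.arange(kh), np.arange(kw), indexing="ij"
        )
        tap = (kz.ravel(), ky.ravel(), kx.ravel())
        K = tap[0].size
        idx = np.empty((od, oh, ow, self.c_in, K), dtype=np.int64)
        for ci in range(self.c_in):
            base = ci * Dp * Hp * Wp
            idx[:, :, :, ci, :] = (
                base
                + (zo[:, None, None, None] + tap[0][None, None, None, :]) * Hp * Wp
                + (yo[None, :, None, None] + tap[1][None, None, None, :]) * Wp
                + (xo[None, None, :, None] + tap[2][None, None, None, :])
            )
        idx = idx.reshape(od * oh * ow, self.c_in * K)
        out = (idx, (od, oh, ow))
        self._index_cache[key] = out
        return out

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        assert C == self.c_in
        pd, ph, pw = self.padding
        if pd or ph or pw:
            xp_data = np.pad(
                x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw))
            )
            orig = x

            def backward(g, _dims=(D, H, W)):
                if orig.requires_grad:
                    d0, h0, w0 = _dims
                    sl = (
                        slice(None),
                        slice(None),
                        slice(pd, pd + d0),
                        slice(ph, ph + h0),
                        slice(pw, pw + w0),
                    )
                    orig._accum(g[sl])

            x = x._child(xp_data, (x,), backward)
            D, H, W = D + 2 * pd, H + 2 * ph, W + 2 * pw
        idx, (od, oh, ow) = self._indices(D, H, W)
        cols = x.gather_flat(idx)  # (B, L, K)
        out = cols @ self.w + self.b  # (B, L, c_out)
        out = out.reshape(B, od, oh, ow, self.c_out)
        return _moveaxis_last_to_c(out)


def _moveaxis_last_to_c(x: Tensor) -> Tensor:
    """(B, D, H, W, C) -> (B, C, D, H, W)."""
    out_data = np.ascontiguousarray(np.moveaxis(x.data, -1, 1))

    def backward(g):
        if x.requires_grad:
            x._accum(np.moveaxis(g, 1, -1))

    return x._child(out_data, (x,), backward)


class MaxPool2d(Module):
    """2x2 in-plane max pooling (depth untouched); requires even H, W."""

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        assert H % 2 == 0 and W % 2 == 0
        r = x.data.reshape(B, C, D, H // 2, 2, W // 2, 2)
        out_data = r.max(axis=(4, 6))
        # argmax mask for backward; ties share the gradient evenly
        mask_f = r == out_data[:, :, :, :, None, :, None]

        def backward(g):
            if not x.requires_grad:
                return
            gg = g[:, :, :, :, None, :, None] * mask_f
            # ties double-count; normalise by number of maxima per window
            counts = mask_f.sum(axis=(4, 6), keepdims=True)
            gg = gg / counts
            x._accum(gg.reshape(x.shape))

        return x._child(out_data, (x,), backward)


class GlobalAvgPool(Module):
    """(B, C, D, H, W) -> (B, C) mean over all spatial positions."""

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[0], x.shape[1]
        return x.reshape(B, C, -1).mean(axis=2)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
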