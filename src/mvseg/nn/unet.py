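"""A configurable 2D U-Net: conv-conv encoder blocks with max pooling, a
bottleneck, transposed-conv upsampling with skip concatenation, and a 1x1
sigmoid head.

The head bias is initialized to the logit of a small foreground prior (1%), a
standard trick for heavily class-imbalanced segmentation that keeps early
training from being dominated by the background term.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, MaxPool2, ReLU, UpConv2

_FG_PRIOR = 0.01


class _DoubleConv:
    """conv3x3 - ReLU - conv3x3 - ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.layers = [
            Conv2D(c_in, c_out, 3, rng),
            ReLU(),
            Conv2D(c_out, c_out, 3, rng),
            ReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class UNet2D:
    """Maps an (h, w) single-channel image to an (h, w) logit map.

    ``depth`` encoder levels double the channel count and halve resolution
    each; ``h`` and ``w`` must be divisible by ``2**depth``.
    """

    def __init__(
        self, depth: int, base_filters: int, input_shape: tuple[int, int], seed: int
    ) -> None:
        if depth < 1 or base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        h, w = input_shape
        if h % (1 << depth) or w % (1 << depth):
            raise ValueError(
                f"input shape {input_shape} not divisible by 2^depth = {1 << depth}"
            )
        self.depth = depth
        self.base_filters = base_filters
        self.input_shape = (int(h), int(w))
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        self.enc: list[_DoubleConv] = []
        c_in = 1
        for lvl in range(depth):
            c_out = base_filters << lvl
            self.enc.append(_DoubleConv(c_in, c_out, rng))
            c_in = c_out
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _DoubleConv(c_in, c_in * 2, rng)
        self.ups: list[UpConv2] = []
        self.dec: list[_DoubleConv] = []
        c = c_in * 2
        for lvl in reversed(range(depth)):
            skip_c = base_filters << lvl
            self.ups.append(UpConv2(c, skip_c, rng))
            self.dec.append(_DoubleConv(2 * skip_c, skip_c, rng))
            c = skip_c
        bias0 = float(np.log(_FG_PRIOR / (1.0 - _FG_PRIOR)))
        self.head = Conv2D(base_filters, 1, 1, rng, bias_init=bias0)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n, h, w, 1) float32 -> logits (n, h, w, 1)."""
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, block, skip_c in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = block.backward(d)
            dskips.append(d[..., :skip_c])
            d = up.backward(d[..., skip_c:])
        d = self.bottleneck.backward(d)
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = block.backward(d)

    # -- parameters ----------------------------------------------------------

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for block in self.enc:
            out.extend(block.params())
        out.extend(self.bottleneck.params())
        for up, block in zip(self.ups, self.dec):
            out.extend(up.params())
            out.extend(block.params())
        out.extend(self.head.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shapes do not match architecture")
            p[...] = w
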