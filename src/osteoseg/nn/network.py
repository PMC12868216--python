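"""A small encoder-decoder segmentation network with skip connections.

Two down/two up levels, 16 base channels, conv-batchnorm-leakyrelu
blocks: large enough to learn the bone/pore phantoms, small enough to
train on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, MaxPool2, ReLU, UpsampleNearest2


def _block(c_in: int, c_out: int, rng) -> list:
    return [
        Conv2d(c_in, c_out, 3, rng), BatchNorm2d(c_out), ReLU(),
        Conv2d(c_out, c_out, 3, rng), BatchNorm2d(c_out), ReLU(),
    ]


def _run(block: list, x: np.ndarray, train: bool) -> np.ndarray:
    for layer in block:
        x = layer.forward(x, train=train)
    return x


def _run_back(block: list, d: np.ndarray) -> np.ndarray:
    for layer in reversed(block):
        d = layer.backward(d)
    return d


class TinyUNet:
    """U-shaped fully convolutional network mapping (N,1,H,W) -> (N,3,H,W).

    H and W must be divisible by 4 (two 2x2 poolings).
    """

    architecture = "tiny_unet"
    backbone = "none"

    def __init__(self, in_channels: int = 1, n_classes: int = 3,
                 base_channels: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base_channels
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_channels = b
        self.enc1 = _block(in_channels, b, rng)
        self.pool1 = MaxPool2()
        self.enc2 = _block(b, 2 * b, rng)
        self.pool2 = MaxPool2()
        self.bott = _block(2 * b, 4 * b, rng)
        self.up1 = UpsampleNearest2()
        self.dec1 = _block(4 * b + 2 * b, 2 * b, rng)
        self.up2 = UpsampleNearest2()
        self.dec2 = _block(2 * b + b, b, rng)
        self.head = Conv2d(b, n_classes, 1, rng)
        self._blocks = [self.enc1, [self.pool1], self.enc2, [self.pool2], self.bott,
                        [self.up1], self.dec1, [self.up2], self.dec2, [self.head]]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N,{self.in_channels},H,W), got {x.shape}")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("H and W must be divisible by 4")
        e1 = _run(self.enc1, x, train)
        e2 = _run(self.enc2, self.pool1.forward(e1, train), train)
        bo = _run(self.bott, self.pool2.forward(e2, train), train)
        d1 = _run(self.dec1, np.concatenate([self.up1.forward(bo, train), e2], axis=1), train)
        d2 = _run(self.dec2, np.concatenate([self.up2.forward(d1, train), e1], axis=1), train)
        return self.head.forward(d2, train)

    def backward(self, dlogits: np.ndarray) -> None:
        b2, b4 = 2 * self.base_channels, 4 * self.base_channels
        d = self.head.backward(dlogits)
        d = _run_back(self.dec2, d)
        d_up2, d_e1 = d[:, :b2], d[:, b2:]
        d = self.up2.backward(d_up2)
        d = _run_back(self.dec1, d)
        d_up1, d_e2 = d[:, :b4], d[:, b4:]
        d = self.up1.backward(d_up1)
        d = _run_back(self.bott, d)
        d = self.pool2.backward(d) + d_e2
        d = _run_back(self.enc2, d)
        d = self.pool1.backward(d) + d_e1
        _run_back(self.enc1, d)

    # -- parameters ---------------------------------------------------------

    def _layers(self) -> list:
        return [layer for block in self._blocks for layer in block]

    def parameters(self) -> list:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def conv_layers(self) -> list[Conv2d]:
        return [l for l in self._layers() if isinstance(l, Conv2d)]

    def param_count(self) -> int:
        """Learnable parameters: conv weights/biases plus batchnorm affine."""
        return sum(int(p.size) for p, _ in self.parameters())

    def flops_forward(self, h: int, w: int, batch: int = 1) -> int:
        """Analytic forward FLOPs (convolution multiply-adds) for one batch."""
        total = 0
        plan = [
            (self.enc1, 1), (self.enc2, 2), (self.bott, 4),
            (self.dec1, 2), (self.dec2, 1), ([self.head], 1),
        ]
        for block, down in plan:
            for layer in block:
                if isinstance(layer, Conv2d):
                    total += layer.flops(h // down, w // down, batch)
        return total

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        ci = bi = 0
        for layer in self._layers():
            if isinstance(layer, Conv2d):
                out[f"conv{ci}.W"] = layer.W
                out[f"conv{ci}.b"] = layer.b
                ci += 1
            elif isinstance(layer, BatchNorm2d):
                out[f"bn{bi}.gamma"] = layer.gamma
                out[f"bn{bi}.beta"] = layer.beta
                out[f"bn{bi}.running_mean"] = layer.running_mean
                out[f"bn{bi}.running_var"] = layer.running_var
                bi += 1
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        ci = bi = 0
        for layer in self._layers():
            if isinstance(layer, Conv2d):
                W = state[f"conv{ci}.W"]
                if W.shape != layer.W.shape:
                    raise ValueError(
                        f"weight shape mismatch at conv{ci}: {W.shape} vs {layer.W.shape}"
                    )
                layer.W[...] = W
                layer.b[...] = state[f"conv{ci}.b"]
                ci += 1
            elif isinstance(layer, BatchNorm2d):
                layer.gamma[...] = state[f"bn{bi}.gamma"]
                layer.beta[...] = state[f"bn{bi}.beta"]
                layer.running_mean[...] = state[f"bn{bi}.running_mean"]
                layer.running_var[...] = state[f"bn{bi}.running_var"]
                bi += 1
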