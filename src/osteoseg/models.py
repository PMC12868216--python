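"""Segmentation architecture registry and model-complexity profiling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .nn import TinyUNet

Architecture = Literal["unet", "unetpp", "deeplabv3plus", "segformer", "tiny_unet"]
Backbone = Literal["resnet18", "resnet50", "efficientnet_b3", "mit_b1", "none"]

#: Valid (architecture, backbone) pairings. ``tiny_unet`` is self-contained;
#: segformer requires a mix-transformer encoder; the remaining architectures
#: accept any convolutional backbone.
VALID_PAIRS: dict[str, tuple[str, ...]] = {
    "tiny_unet": ("none",),
    "unet": ("resnet18", "resnet50", "efficientnet_b3", "mit_b1"),
    "unetpp": ("resnet18", "resnet50", "efficientnet_b3", "mit_b1"),
    "deeplabv3plus": ("resnet18", "resnet50", "efficientnet_b3"),
    "segformer": ("mit_b1",),
}


class ModelConfigurationError(ValueError):
    """Invalid architecture/backbone pairing or initialization."""


class MissingDependencyError(ImportError):
    """A third-party architecture was requested but its library is absent."""


@dataclass(frozen=True)
class ModelSpec:
    architecture: Architecture = "tiny_unet"
    backbone: Backbone = "none"
    n_classes: int = 3
    in_channels: int = 1
    init: str = "random"  # "random", "imagenet", or "file:<path>"

    def __post_init__(self) -> None:
        if self.architecture not in VALID_PAIRS:
            raise ModelConfigurationError(
                f"unknown architecture {self.architecture!r}; valid: {sorted(VALID_PAIRS)}"
            )
        if self.backbone not in VALID_PAIRS[self.architecture]:
            raise ModelConfigurationError(
                f"backbone {self.backbone!r} is not valid for {self.architecture!r}; "
                f"valid pairs: {self.architecture} x {VALID_PAIRS[self.architecture]}"
            )


@dataclass(frozen=True)
class ComplexityProfile:
    """Forward-pass FLOPs on one batch and total parameter count."""

    flops_forward: int
    param_count: int

    def __post_init__(self) -> None:
        if self.flops_forward <= 0 or self.param_count <= 0:
            raise ValueError("complexity counts must be positive")


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the model for *spec*.

    ``tiny_unet`` is always available (pure NumPy). The third-party
    architectures require ``segmentation_models_pytorch`` and raise
    :class:`MissingDependencyError` when it is not installed.
    """
    if spec.architecture == "tiny_unet":
        return TinyUNet(in_channels=spec.in_channels, n_classes=spec.n_classes, seed=seed)
    try:
        import segmentation_models_pytorch as smp  # type: ignore
    except ImportError as exc:
        raise MissingDependencyError(
            f"architecture {spec.architecture!r} requires segmentation_models_pytorch; "
            "install it or use architecture='tiny_unet'"
        ) from exc
    cls = {
        "unet": smp.Unet,
        "unetpp": smp.UnetPlusPlus,
        "deeplabv3plus": smp.DeepLabV3Plus,
        "segformer": smp.Segformer,
    }[spec.architecture]
    encoder_weights = "imagenet" if spec.init == "imagenet" else None
    return cls(
        encoder_name=spec.backbone,
        encoder_weights=encoder_weights,
        in_channels=spec.in_channels,
        classes=spec.n_classes,
    )


def profile_model(handle, sample_batch: np.ndarray) -> ComplexityProfile:
    """Forward FLOPs on *sample_batch* plus total parameter count.

    Deterministic for a fixed model and batch shape. For the NumPy
    network the counts are analytic (convolution multiply-adds, 2 FLOPs
    each); pooling/activation costs are negligible and excluded.
    """
    n, _, h, w = np.asarray(sample_batch).shape
    if isinstance(handle, TinyUNet):
        return ComplexityProfile(
            flops_forward=handle.flops_forward(h, w, batch=n),
            param_count=handle.param_count(),
        )
    # torch path: parameter count from the module; FLOPs via fvcore if present
    param_count = sum(int(np.prod(p.shape)) for p in handle.parameters())
    try:
        import torch  # type: ignore
        from fvcore.nn import FlopCountAnalysis  # type: ignore

        flops = int(FlopCountAnalysis(handle, torch.as_tensor(sample_batch)).total()) * 2
    except ImportError as exc:
        raise MissingDependencyError(
            "profiling third-party models requires torch and fvcore"
        ) from exc
    return ComplexityProfile(flops_forward=flops, param_count=param_count)
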