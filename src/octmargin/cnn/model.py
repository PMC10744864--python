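"""Architecture of the compact grayscale patch classifier.

The classifier follows a VGG-like template fixed to exactly five 3×3
convolutional layers (each followed by ReLU and 2×2 max-pooling) and three
fully connected layers operating on 1-channel 420×188 patches. The layer
widths are free parameters; the defaults are chosen so the trainable
parameter count lands on the ~1,589,000 budget of an edge-deployable model
while keeping the forward pass around 60 MFLOP per patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from octmargin.cnn import engine

__all__ = ["ArchConfig", "count_parameters", "build_model", "PatchCNN", "conv_output_shape"]

N_CONV = 5
N_FC = 3


@dataclass(frozen=True)
class ArchConfig:
    """Widths and options of the 5-conv + 3-FC architecture.

    ``fc_sizes`` lists the three fully connected layer widths; the last entry
    is the logit count (2 for the softmax binary head, 1 for a sigmoid head).
    """

    conv_channels: tuple[int, ...] = (4, 8, 16, 32, 32)
    fc_sizes: tuple[int, ...] = (705, 150, 2)
    input_shape: tuple[int, int, int] = (420, 188, 1)  # H, W, C
    pool_after: tuple[bool, ...] = (True, True, True, True, True)
    dropout_rate: float = 0.5  # VGG-style dropout before the hidden FC layers
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_channels) != N_CONV:
            raise ValueError(f"exactly {N_CONV} convolutional layers are required")
        if len(self.fc_sizes) != N_FC:
            raise ValueError(f"exactly {N_FC} fully connected layers are required")
        if len(self.pool_after) != N_CONV:
            raise ValueError("pool_after must list one flag per conv layer")
        if self.kernel_size != 3:
            raise ValueError("the architecture is fixed to 3x3 kernels")
        if any(c < 1 for c in self.conv_channels) or any(f < 1 for f in self.fc_sizes):
            raise ValueError("layer widths must be positive")
        if self.fc_sizes[-1] not in (1, 2):
            raise ValueError("the final layer must emit 1 or 2 logits")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def conv_output_shape(arch: ArchConfig) -> tuple[int, int, int]:
    """(H, W, C) of the last conv stage's output after its pooling."""
    h, w, _ = arch.input_shape
    for channels, pool in zip(arch.conv_channels, arch.pool_after):
        if pool:
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError("spatial size collapsed to zero before the FC stage")
    return h, w, arch.conv_channels[-1]


def count_parameters(arch: ArchConfig) -> int:
    """Closed-form trainable parameter count.

    Each 3×3 conv contributes ``9·c_in·c_out + c_out``; each FC layer
    ``n_in·n_out + n_out``. Equals the framework-introspected count of the
    built model (property-tested).
    """
    total = 0
    c_in = arch.input_shape[2]
    for c_out in arch.conv_channels:
        total += 9 * c_in * c_out + c_out
        c_in = c_out
    h, w, c = conv_output_shape(arch)
    n_in = h * w * c
    for n_out in arch.fc_sizes:
        total += n_in * n_out + n_out
        n_in = n_out
    return total


class PatchCNN(engine.Network):
    """The built classifier: engine network + architecture bookkeeping."""

    def __init__(self, arch: ArchConfig, layers: list, last_conv_relu_index: int):
        super().__init__(layers)
        self.arch = arch
        self._last_conv_relu = last_conv_relu_index

    # -- introspection ------------------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    # -- inference ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Suspicious-class probability per sample, float64 in [0, 1]."""
        logits = self.forward(x.astype(np.float32), train=False)
        if logits.shape[1] == 1:
            return 1.0 / (1.0 + np.exp(-logits[:, 0].astype(np.float64)))
        return engine.softmax(logits.astype(np.float64))[:, 1]

    # -- Grad-CAM hook ------------------------------------------------------
    def last_conv_activation_and_grad(
        self, x: np.ndarray, target_class: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Post-ReLU feature maps of the last conv layer and the gradient of
        the target-class logit with respect to them, for a batch."""
        logits = self.forward(x.astype(np.float32), train=False)
        act = self._forward_upto(x.astype(np.float32))
        dlogits = np.zeros_like(logits)
        if logits.shape[1] == 1:
            dlogits[:, 0] = 1.0 if target_class == 1 else -1.0
        else:
            dlogits[:, target_class] = 1.0
        grad = self.backward(dlogits, stop_at=self._last_conv_relu + 1)
        return act, grad

    def _forward_upto(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[: self._last_conv_relu + 1]:
            x = layer.forward(x, train=False)
        return x


def build_model(arch: ArchConfig = ArchConfig(), seed: int = 0) -> PatchCNN:
    """Instantiate the classifier with He-initialized weights.

    Raises at build time when the conv/pool stack and the FC stage are
    dimensionally inconsistent (e.g. spatial size collapsing to zero).
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = arch.input_shape[2]
    last_conv_relu = -1
    for i, (channels, pool) in enumerate(zip(arch.conv_channels, arch.pool_after)):
        layers.append(engine.Conv2D(c_in, channels, rng, needs_input_grad=i > 0))
        layers.append(engine.ReLU())
        last_conv_relu = len(layers) - 1
        if pool:
            layers.append(engine.MaxPool2())
        c_in = channels
    layers.append(engine.Flatten())
    h, w, c = conv_output_shape(arch)
    n_in = h * w * c
    for i, n_out in enumerate(arch.fc_sizes):
        if arch.dropout_rate > 0 and i < N_FC - 1:
            layers.append(engine.Dropout(arch.dropout_rate, rng))
        layers.append(engine.Dense(n_in, n_out, rng))
        if i < N_FC - 1:
            layers.append(engine.ReLU())
        n_in = n_out
    model = PatchCNN(arch, layers, last_conv_relu)
    assert model.n_parameters() == count_parameters(arch)
    return model
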