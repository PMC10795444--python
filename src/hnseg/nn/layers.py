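"""Neural-network layers and the Adam optimizer, built on `hnseg.nn.autograd`."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    conv2d,
    conv_transpose2x2,
    depthwise_conv2d,
    matmul,
    relu,
    replicate_pad2d,
    sigmoid,
)

__all__ = [
    "Module",
    "Conv2d",
    "DepthwiseSeparableConv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "Linear",
    "Adam",
]


class Module:
    """Base class: tracks parameters and sub-modules, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- flat state (weights + buffers) for checkpointing ----------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, m in self._named_modules(""):
            if isinstance(m, BatchNorm2d):
                state[name + ".running_mean"] = m.running_mean.copy()
                state[name + ".running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value, dtype=np.float64).copy()
        for name, m in self._named_modules(""):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(
                    state[name + ".running_mean"], dtype=np.float64).copy()
                m.running_var = np.asarray(
                    state[name + ".running_var"], dtype=np.float64).copy()

    def _named_modules(self, prefix: str) -> list[tuple[str, "Module"]]:
        out = [(prefix.rstrip("."), self)] if prefix else [("", self)]
        for name, m in self._modules.items():
            out.extend(m._named_modules(prefix + name + "."))
        return out


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, pad: int | None = None,
                 bias: bool = True, pad_mode: str = "zeros"):
        super().__init__()
        self.pad = kernel // 2 if pad is None else pad
        self.pad_mode = pad_mode
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                               in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.pad_mode == "replicate" and self.pad > 0:
            return conv2d(replicate_pad2d(x, self.pad), self.weight,
                          self.bias, pad=0)
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class DepthwiseSeparableConv2d(Module):
    """3x3 depthwise convolution followed by a 1x1 pointwise convolution."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.dw_weight = _he_init(rng, (in_ch, kernel, kernel),
                                  kernel * kernel)
        self.pad = kernel // 2
        self.pointwise = Conv2d(in_ch, out_ch, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pointwise(depthwise_conv2d(x, self.dw_weight, pad=self.pad))


class ConvTranspose2x2(Module):
    """Learned 2x upsampling (kernel 2, stride 2 transposed convolution)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Uses batch statistics in training mode and exponential running
    estimates (momentum 0.1) at inference, so prediction is a
    deterministic function of the weights alone.
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.calibrating = False
        self._acc = None

    def start_calibration(self) -> None:
        """Begin exact-statistics accumulation ("precise BN")."""
        self.calibrating = True
        self._acc = [np.zeros_like(self.running_mean),
                     np.zeros_like(self.running_var), 0]

    def finish_calibration(self) -> None:
        s, sq, n = self._acc
        if n > 0:
            mean = s / n
            self.running_mean = mean
            self.running_var = sq / n - mean**2
        self.calibrating = False
        self._acc = None

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            if self.calibrating:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                self._acc[0] += x.data.sum(axis=(0, 2, 3))
                self._acc[1] += (x.data**2).sum(axis=(0, 2, 3))
                self._acc[2] += n
            else:
                self.running_mean = (1 - self.momentum) * self.running_mean \
                    + self.momentum * mu.data.ravel()
                self.running_var = (1 - self.momentum) * self.running_var + \
                    self.momentum * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = _he_init(rng, (in_f, out_f), in_f)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        return y + self.bias if self.bias is not None else y


class Adam:
    """Adam optimizer; `lr` may be reassigned between steps (scheduling)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# re-exported activations for convenience
__all__ += ["relu", "sigmoid"]
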