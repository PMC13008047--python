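"""Module/parameter layer over the autograd core, plus AdamW.

Modules hold :class:`Parameter` leaves and child modules as plain
attributes; :meth:`Module.named_parameters` walks the attribute tree.
Every layer takes an ``rng`` (``numpy.random.Generator``) at construction
so a model built from a seed has bit-reproducible initial weights.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, conv2d, depthwise_conv1d_causal


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter traversal -------------------------------------------------

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- mode / gradient management ------------------------------------------

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self):
        return sum(p.size for p in self.parameters())

    # -- state dict -----------------------------------------------------------

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].data.shape} vs {arr.shape}")
                params[name].data = np.ascontiguousarray(arr, dtype=np.float32)
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name}")

    def named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


# ---------------------------------------------------------------------------
# initialisation


def _kaiming_uniform(rng, shape, fan_in):
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# layers


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(_kaiming_uniform(rng, (out_features,), in_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 stride=1, padding=0, dilation=1, bias=True):
        super().__init__()
        k = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_channels * k[0] * k[1]
        self.weight = Parameter(_kaiming_uniform(rng, (out_channels, in_channels, *k), fan_in))
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class ChannelConv1d(Module):
    """1-D convolution applied across a per-channel descriptor vector.

    Treats a (B, C) descriptor as a length-C signal with a single feature
    channel, as used by the channel-attention recalibrations.
    """

    def __init__(self, kernel_size, rng, bias=True):
        super().__init__()
        self.k = kernel_size
        self.pad = kernel_size // 2
        self.weight = Parameter(_kaiming_uniform(rng, (kernel_size,), kernel_size))
        self.bias = Parameter(np.zeros(1, np.float32)) if bias else None

    def forward(self, x):
        # x: (B, C) -> same shape; implemented with the 2-D conv primitive
        b, c = x.shape
        x4 = x.reshape(b, 1, 1, c)
        w = self.weight.reshape(1, 1, 1, self.k)
        out = conv2d(x4, w, None, padding=(0, self.pad))
        out = out.reshape(b, c)
        if self.bias is not None:
            out = out + self.bias
        return out


class CausalDepthwiseConv1d(Module):
    """Depthwise causal convolution over token sequences (B, C, L)."""

    def __init__(self, channels, kernel_size, rng, bias=True):
        super().__init__()
        self.weight = Parameter(_kaiming_uniform(rng, (channels, kernel_size), kernel_size))
        self.bias = Parameter(np.zeros(channels, np.float32)) if bias else None

    def forward(self, x):
        return depthwise_conv1d_causal(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalisation over the trailing feature axis (per token)."""

    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, np.float32))
        self.bias = Parameter(np.zeros(dim, np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            xc = x - mu
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class GroupNorm(Module):
    def __init__(self, num_groups, channels, eps=1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError("channels must be divisible by num_groups")
        self.g, self.eps = num_groups, eps
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))

    def forward(self, x):
        b, c, h, w = x.shape
        xg = x.reshape(b, self.g, c // self.g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        xhat = (xc * (var + self.eps) ** -0.5).reshape(b, c, h, w)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


# ---------------------------------------------------------------------------
# optimiser


class AdamW:
    """Decoupled weight-decay Adam (the training configuration's optimiser)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
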