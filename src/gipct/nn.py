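"""Bias-free convolutional denoising network with certified spectral norms.

A deliberately small numpy implementation: the network is a chain of
zero-padded "same" convolutions with no additive constants anywhere,
interleaved with ReLU nonlinearities,

    f(x) = W_N R(W_{N-1} ... R(W_1 x)),

so f(0) = 0 exactly and, because ReLU is positively homogeneous, the map is
locally linear: f(x) = J(x) x with J the input Jacobian. Each layer is a
linear operator on full image tensors; its Lipschitz constant is its
spectral norm, estimated by power iteration on (layer adjoint o layer), and
the product of the per-layer norms upper-bounds the network's Lipschitz
constant (composition of Lipschitz maps). The gradient of a layer's leading
singular value sigma = u^T W v with respect to the kernel reuses the
convolution weight-gradient routine with u as the output cotangent and v as
the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvLayer", "BiasFreeNet", "SpectralState", "layer_spectral_norm", "Adam"]


class ConvLayer:
    """Zero-padded stride-1 'same' 2D convolution, no bias.

    kernel shape: (out_ch, in_ch, k, k) with odd k. Acts on tensors of
    shape (batch, in_ch, H, W).
    """

    def __init__(self, kernel: np.ndarray):
        kernel = np.asarray(kernel, dtype=np.float64)
        if kernel.ndim != 4 or kernel.shape[2] != kernel.shape[3] or kernel.shape[2] % 2 == 0:
            raise ValueError("kernel must have shape (out_ch, in_ch, k, k) with odd k")
        self.kernel = kernel

    @property
    def out_ch(self):
        return self.kernel.shape[0]

    @property
    def in_ch(self):
        return self.kernel.shape[1]

    @property
    def ksize(self):
        return self.kernel.shape[2]

    def _cols(self, x: np.ndarray) -> np.ndarray:
        """im2col: (batch, H, W, in_ch*k*k) patch matrix of the padded input."""
        k = self.ksize
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (batch, in_ch, H, W, k, k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        b, c, h, w = x.shape[0], x.shape[1], x.shape[2], x.shape[3]
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h, w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError("channel mismatch")
        cols = self._cols(x)
        kmat = self.kernel.reshape(self.out_ch, -1)
        out = cols @ kmat.T  # (b, h, w, out_ch)
        return out.transpose(0, 3, 1, 2)

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        """Transpose of ``forward``: same-padded convolution with the
        spatially flipped kernel and swapped channel axes."""
        k_flip = self.kernel[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return ConvLayer(np.ascontiguousarray(k_flip)).forward(g)

    def grad_kernel(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Gradient of sum(g * forward(x)) with respect to the kernel."""
        cols = self._cols(x)  # (b, h, w, in_ch*k*k)
        gm = g.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)  # (bhw, out_ch)
        gk = gm.T @ cols.reshape(-1, cols.shape[-1])
        return gk.reshape(self.kernel.shape)


def layer_spectral_norm(
    layer: ConvLayer,
    input_shape: tuple,
    n_iters: int = 100,
    v0: np.ndarray | None = None,
):
    """Leading singular value of the layer acting on full input tensors.

    Power iteration on (adjoint o layer): v_{j+1} = A^T A v_j / ||.||, with
    sigma = ||A v||. Warm-startable via ``v0``. Returns (sigma, u, v) where
    u = A v / ||A v|| — the pair needed for the singular-value gradient.
    A zero layer returns sigma = 0.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    c, h, w = input_shape
    rng = np.random.default_rng(0)
    v = rng.standard_normal((1, c, h, w)) if v0 is None else v0.copy()
    nv = np.linalg.norm(v)
    if nv == 0:
        v = rng.standard_normal((1, c, h, w))
        nv = np.linalg.norm(v)
    v /= nv
    sigma = 0.0
    u = None
    for _ in range(n_iters):
        av = layer.forward(v)
        sigma = float(np.linalg.norm(av))
        if sigma == 0.0:
            return 0.0, np.zeros_like(av), v
        u = av / sigma
        v = layer.adjoint(u)
        nv = np.linalg.norm(v)
        if nv == 0:
            return 0.0, u, v
        v /= nv
    return sigma, u, v


@dataclass
class SpectralState:
    """Per-layer power-iteration bookkeeping for a BiasFreeNet.

    Holds the warm-started leading right-singular-vector estimates, the
    per-layer spectral-norm estimates and their product.
    """

    norms: list = field(default_factory=list)
    vectors: list = field(default_factory=list)
    singular_pairs: list = field(default_factory=list)  # (u, v) per layer

    @property
    def product(self) -> float:
        return float(np.prod(self.norms)) if self.norms else 0.0

    def update(self, net: "BiasFreeNet", n_iters: int = 3) -> float:
        """Refresh all per-layer estimates with warm-started power steps."""
        if not self.vectors:
            self.vectors = [None] * len(net.layers)
        self.norms = []
        self.singular_pairs = []
        for i, (layer, shape) in enumerate(zip(net.layers, net.input_shapes)):
            sigma, u, v = layer_spectral_norm(layer, shape, n_iters=n_iters, v0=self.vectors[i])
            self.vectors[i] = v
            self.norms.append(sigma)
            self.singular_pairs.append((u, v))
        return self.product


class BiasFreeNet:
    """Chain of bias-free 'same' convolutions with ReLU between them.

    Parameters
    ----------
    channels : sequence of int
        Channel widths including input and output, e.g. (1, 16, 16, 1).
    ksize : int
        Odd spatial kernel size for every layer.
    image_shape : (H, W)
        Working image size (fixes the linear-operator domain used for
        spectral-norm certification; the forward pass itself accepts any
        spatial size).
    init_norm : float
        Target per-layer spectral norm at initialization; kernels are drawn
        Gaussian and rescaled so the initial product is about
        ``init_norm ** n_layers``.
    skip_gain : float or None
        If set, adds a learnable scaled identity skip from input to output,
        f(x) = a*x + chain(x), initialized at this value. The certified
        Lipschitz bound becomes |a| + prod_l L(W_l) (triangle inequality);
        f(0) = 0 and positive homogeneity are preserved.
    init_mode : {"identity", "random"}
        identity — start at a pass-through chain (channel 0 carries the
        image; ReLU is inactive on positive inputs) perturbed by small
        random kernels, so training begins at a near-identity denoiser and
        descends from there; random — spectrally rescaled Gaussian kernels.
    """

    def __init__(
        self,
        channels=(1, 16, 16, 16, 1),
        ksize: int = 3,
        image_shape=(32, 32),
        seed: int = 0,
        init_norm: float = 0.95,
        skip_gain: float | None = None,
        init_mode: str = "identity",
    ):
        rng = np.random.default_rng(seed)
        self.channels = tuple(int(c) for c in channels)
        self.image_shape = tuple(image_shape)
        self.skip_gain = None if skip_gain is None else float(skip_gain)
        if self.skip_gain is not None and self.channels[0] != self.channels[-1]:
            raise ValueError("identity skip requires matching input/output channels")
        if init_mode not in ("identity", "random"):
            raise ValueError("init_mode must be 'identity' or 'random'")
        self.layers = []
        h, w = self.image_shape
        self.input_shapes = []
        n_layers = len(self.channels) - 1
        per_layer = init_norm ** (1.0 / n_layers)
        for cin, cout in zip(self.channels[:-1], self.channels[1:]):
            if init_mode == "identity":
                kernel = 0.03 * rng.standard_normal((cout, cin, ksize, ksize)) / np.sqrt(cin * ksize * ksize)
                kernel[0, 0, ksize // 2, ksize // 2] += per_layer
            else:
                kernel = rng.standard_normal((cout, cin, ksize, ksize))
                kernel /= np.sqrt(cin * ksize * ksize)
            layer = ConvLayer(kernel)
            sigma, _, _ = layer_spectral_norm(layer, (cin, h, w), n_iters=50)
            if sigma > 0:
                layer.kernel *= per_layer / sigma
            self.layers.append(layer)
            self.input_shapes.append((cin, h, w))

    @property
    def n_params(self) -> int:
        return int(sum(l.kernel.size for l in self.layers))

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Apply the network to (batch, in_ch, H, W) or a bare 2D image."""
        squeeze = False
        if x.ndim == 2:
            x = x[None, None]
            squeeze = True
        out = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            if cache is not None:
                cache.append(out)
            out = layer.forward(out)
            if i < last:
                if cache is not None:
                    cache.append(out)  # pre-activation, for the ReLU mask
                out = np.maximum(out, 0.0)
        if self.skip_gain is not None:
            out = out + self.skip_gain * x
        return out[0, 0] if squeeze else out

    def __call__(self, x):
        return self.forward(x)

    def backward(self, cache: list, g_out: np.ndarray):
        """Backprop through a cached forward pass.

        Returns (kernel gradients per layer, gradient w.r.t. the input).
        With a skip connection the scalar gain's gradient is available as
        ``self.last_skip_grad``. ``cache`` is the list filled by
        ``forward``: alternating layer inputs and pre-activations.
        """
        grads = [None] * len(self.layers)
        g = g_out
        ci = len(cache) - 1
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                pre = cache[ci]
                ci -= 1
                g = g * (pre > 0)
            x_in = cache[ci]
            ci -= 1
            grads[i] = self.layers[i].grad_kernel(x_in, g)
            g = self.layers[i].adjoint(g)
        if self.skip_gain is not None:
            x0 = cache[0]
            self.last_skip_grad = float(np.sum(g_out * x0))
            g = g + self.skip_gain * g_out
        return grads, g

    def input_gradient(self, x: np.ndarray, g_out: np.ndarray) -> np.ndarray:
        """Vector-Jacobian product J(x)^T g_out, for a single 2D image."""
        cache = []
        self.forward(x[None, None], cache=cache)
        _, g_in = self.backward(cache, g_out[None, None])
        return g_in[0, 0]

    def certified_bound(self, norms) -> float:
        """Lipschitz certificate from per-layer norms: their product, plus
        |skip_gain| when the identity skip is enabled (triangle inequality)."""
        product = float(np.prod(norms))
        if self.skip_gain is not None:
            return abs(self.skip_gain) + product
        return product

    def copy(self) -> "BiasFreeNet":
        other = object.__new__(BiasFreeNet)
        other.channels = self.channels
        other.image_shape = self.image_shape
        other.skip_gain = self.skip_gain
        other.layers = [ConvLayer(l.kernel.copy()) for l in self.layers]
        other.input_shapes = list(self.input_shapes)
        return other


class Adam:
    """Adam optimizer over the list of layer kernels."""

    # eps far below float noise keeps the update scale-invariant: gradients
    # of a physically scaled loss (~1e-12) must not be swamped by eps
    def __init__(self, net: BiasFreeNet, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-30):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(l.kernel) for l in net.layers]
        self.v = [np.zeros_like(l.kernel) for l in net.layers]
        self.t = 0

    def step(self, grads: list):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, g) in enumerate(zip(self.net.layers, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.kernel -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
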