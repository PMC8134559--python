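"""Black-box regressor contract and closed-form surrogate regressors.

The probe in :mod:`pdprobe.saliency` treats a bone-age model as an opaque
function from a packed 299x299x3 integer image to a scalar age in months.
Anything exposing that contract — a wrapped neural network, a remote
service, or one of the surrogates below — can be probed.

Surrogates are analytic stand-ins with closed-form gradients.  They exist
so the finite-difference machinery can be validated against exact oracles
without a trained network: a linear form makes the forward difference
exact, a quadratic form exposes the forward-difference bias, and a smooth
bounded bump exercises the curvature error bound.

Weight draws for the linear, quadratic and regional-sum surrogates are
quantized to dyadic rationals (integer multiples of a power of two).  With
that quantization every product weight*intensity and every partial sum in
the dot product is exactly representable in IEEE double precision, so the
difference quotient ``predict(x + e) - predict(x)`` reproduces the
analytic gradient with *zero* floating-point error — the property the
linear-oracle tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

#: Model-input geometry: 299x299 pixels, 3 channels, intensities 0-254
#: (the probe's +1 step may present 255; models must accept it).
PACKED_SHAPE = (299, 299, 3)

#: Quantum for linear / regional-sum weights (multiples of 2**-40).
_Q_LINEAR = 2.0 ** -40
#: Quantum for quadratic coefficients (multiples of 2**-30; the x**2
#: factor is up to 255**2 so a coarser quantum keeps sums exact).
_Q_QUAD = 2.0 ** -30

_KINDS = ("constant", "linear", "quadratic", "radial-bump", "regional-sum")


@runtime_checkable
class Regressor(Protocol):
    """Contract every probe-able model satisfies.

    ``predict`` must be deterministic (bit-identical output for identical
    input grids) and accept channel intensities in [0, 255].  Stochastic
    models (dropout at inference, nondeterministic kernels) must be
    wrapped into a fixed-mode deterministic form by the caller.
    """

    metadata: dict

    def predict(self, image: np.ndarray) -> float:  # pragma: no cover
        ...


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for a surrogate regressor.

    Identical (kind, seed, params) always rebuild the identical surrogate;
    randomized parameters are drawn from ``numpy.random.default_rng(seed)``.
    """

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(
                f"unknown surrogate kind {self.kind!r}; expected one of {_KINDS}"
            )


def _quantize(values: np.ndarray | float, quantum: float) -> np.ndarray:
    return np.round(np.asarray(values, dtype=np.float64) / quantum) * quantum


def _as_input(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image, dtype=np.float64)
    if x.shape != PACKED_SHAPE:
        raise ValueError(f"expected image of shape {PACKED_SHAPE}, got {x.shape}")
    return x


class _Surrogate:
    """Base class: deterministic predict + loop-based batch predict.

    ``predict_batch`` deliberately evaluates ``predict`` per image rather
    than vectorizing across the batch, so batched and sequential probing
    are bit-identical by construction.
    """

    kind: str = ""
    #: Upper bound on |d^2/dt^2 f(x + t*u)| where u increments all three
    #: channels of one pixel by one (the probe direction).  Zero for
    #: constant/linear/regional-sum.
    curvature_bound: float = 0.0

    def __init__(self, spec: SurrogateSpec):
        self.spec = spec
        self.metadata = {"name": f"surrogate:{spec.kind}", "seed": spec.seed}

    def predict(self, image: np.ndarray) -> float:
        raise NotImplementedError

    def predict_batch(self, images) -> np.ndarray:
        return np.array([self.predict(im) for im in images], dtype=np.float64)

    def gradient(self, image: np.ndarray) -> np.ndarray:
        """Closed-form d(predict)/d(intensity) at ``image``, shape 299x299x3."""
        raise NotImplementedError


class ConstantSurrogate(_Surrogate):
    kind = "constant"

    def __init__(self, spec: SurrogateSpec):
        super().__init__(spec)
        self.value = float(spec.params.get("value", 120.0))

    def predict(self, image: np.ndarray) -> float:
        _as_input(image)
        return self.value

    def gradient(self, image: np.ndarray) -> np.ndarray:
        _as_input(image)
        return np.zeros(PACKED_SHAPE)


class LinearSurrogate(_Surrogate):
    """f(x) = sum_{p,ch} w_{p,ch} x_{p,ch} + b.

    Default weights are uniform on [-1e-4, 1e-4] (quantized), which puts
    in-mask PD magnitudes in the 1e-4..3e-4 band — the same display
    decade the sigmoid overlay is tuned for.
    """

    kind = "linear"

    def __init__(self, spec: SurrogateSpec, weights: np.ndarray | None = None):
        super().__init__(spec)
        scale = float(spec.params.get("scale", 1e-4))
        if weights is None:
            rng = np.random.default_rng(spec.seed)
            weights = rng.uniform(-scale, scale, size=PACKED_SHAPE)
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != PACKED_SHAPE:
            raise ValueError(
                f"weight grid shape {weights.shape} != {PACKED_SHAPE}"
            )
        self.weights = _quantize(weights, _Q_LINEAR)
        self.bias = float(_quantize(spec.params.get("bias", 100.0), _Q_LINEAR))
        self._wflat = np.ascontiguousarray(self.weights.ravel())

    def predict(self, image: np.ndarray) -> float:
        x = _as_input(image)
        return float(self._wflat @ x.ravel() + self.bias)

    def gradient(self, image: np.ndarray) -> np.ndarray:
        _as_input(image)
        return self.weights.copy()


class QuadraticSurrogate(_Surrogate):
    """f(x) = sum a_{p,ch} x_{p,ch}^2 — the forward-difference-bias fixture."""

    kind = "quadratic"

    def __init__(self, spec: SurrogateSpec):
        super().__init__(spec)
        scale = float(spec.params.get("scale", 1e-6))
        rng = np.random.default_rng(spec.seed)
        self.coeffs = _quantize(
            rng.uniform(-scale, scale, size=PACKED_SHAPE), _Q_QUAD
        )
        self._aflat = np.ascontiguousarray(self.coeffs.ravel())
        # d2f/dt2 along the probe direction is 2*(a1+a2+a3).
        self.curvature_bound = float(
            2.0 * np.max(np.abs(self.coeffs.sum(axis=2)))
        )

    def predict(self, image: np.ndarray) -> float:
        x = _as_input(image)
        xf = x.ravel()
        return float(self._aflat @ (xf * xf))

    def gradient(self, image: np.ndarray) -> np.ndarray:
        x = _as_input(image)
        return 2.0 * self.coeffs * x


class RadialBumpSurrogate(_Surrogate):
    """Smooth bounded bump of a radially weighted pixel sum.

    f(x) = A * exp(-(v - v0)^2 / 2) with v = (c . x) / s0, where c is a
    Gaussian spatial kernel (identical across the three channels) centred
    at ``center`` with width ``rho``, and s0 normalizes v to be ~1 on a
    mid-gray image.  Bounded, infinitely differentiable, and its second
    derivative along the probe direction is bounded by
    ``A * (3 * c_max / s0)^2`` (since ``max |h''| = 1`` for the Gaussian
    h), giving a certified forward-difference error bound.
    """

    kind = "radial-bump"

    def __init__(self, spec: SurrogateSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        p = spec.params
        r0 = float(p.get("row", rng.uniform(100, 200)))
        c0 = float(p.get("col", rng.uniform(100, 200)))
        self.center = (r0, c0)
        self.rho = float(p.get("rho", 60.0))
        self.amplitude = float(p.get("amplitude", 24.0))
        self.v0 = float(p.get("v0", 1.0))
        rr, cc = np.mgrid[0 : PACKED_SHAPE[0], 0 : PACKED_SHAPE[1]]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        kern = np.exp(-d2 / (2.0 * self.rho**2))
        self.kernel = np.repeat(kern[:, :, None], 3, axis=2)
        # v ~= 1 for a uniform mid-gray (127) image.
        self.s0 = float(127.0 * self.kernel.sum())
        self._kflat = np.ascontiguousarray(self.kernel.ravel())
        cmax = float(kern.max())
        self.curvature_bound = self.amplitude * (3.0 * cmax / self.s0) ** 2

    def _v(self, x: np.ndarray) -> float:
        return float(self._kflat @ x.ravel()) / self.s0

    def predict(self, image: np.ndarray) -> float:
        v = self._v(_as_input(image))
        return self.amplitude * float(np.exp(-0.5 * (v - self.v0) ** 2))

    def gradient(self, image: np.ndarray) -> np.ndarray:
        v = self._v(_as_input(image))
        h_prime = -(v - self.v0) * np.exp(-0.5 * (v - self.v0) ** 2)
        return (self.amplitude * h_prime / self.s0) * self.kernel


class RegionalSumSurrogate(LinearSurrogate):
    """Weighted sum of intensities inside supplied label regions.

    A linear form whose weight grid is piecewise constant on an integer
    label map: every pixel of region r (all three channels) carries
    weight w_r; unlabeled pixels carry zero.
    """

    kind = "regional-sum"

    def __init__(self, spec: SurrogateSpec, labels: np.ndarray | None = None):
        if labels is None:
            labels = spec.params.get("labels")
        if labels is None:
            raise ValueError("regional-sum surrogate requires a 299x299 label map")
        labels = np.asarray(labels)
        if labels.shape != PACKED_SHAPE[:2]:
            raise ValueError(
                f"label map shape {labels.shape} != {PACKED_SHAPE[:2]}"
            )
        n_labels = int(labels.max())
        weights_per_label = spec.params.get("weights")
        if weights_per_label is None:
            rng = np.random.default_rng(spec.seed)
            mags = rng.uniform(1e-5, 1e-4, size=n_labels)
            signs = rng.choice([-1.0, 1.0], size=n_labels)
            weights_per_label = mags * signs
        w = np.zeros(n_labels + 1)
        w[1:] = _quantize(np.asarray(weights_per_label, dtype=np.float64)[:n_labels],
                          _Q_LINEAR)
        grid = np.repeat(w[labels][:, :, None], 3, axis=2)
        super().__init__(
            SurrogateSpec("linear", seed=spec.seed, params={"bias": spec.params.get("bias", 0.0)}),
            weights=grid,
        )
        self.spec = spec
        self.kind = "regional-sum"
        self.labels = labels.copy()
        self.label_weights = w
        self.metadata = {"name": "surrogate:regional-sum", "seed": spec.seed}


_BUILDERS = {
    "constant": ConstantSurrogate,
    "linear": LinearSurrogate,
    "quadratic": QuadraticSurrogate,
    "radial-bump": RadialBumpSurrogate,
    "regional-sum": RegionalSumSurrogate,
}


def make_surrogate(spec: SurrogateSpec) -> _Surrogate:
    """Build the surrogate regressor a spec describes."""
    return _BUILDERS[spec.kind](spec)


def analytic_gradient(model_or_spec, image: np.ndarray) -> np.ndarray:
    """Closed-form per-pixel-per-channel gradient of a surrogate at ``image``."""
    model = (
        make_surrogate(model_or_spec)
        if isinstance(model_or_spec, SurrogateSpec)
        else model_or_spec
    )
    return model.gradient(image)


# ---------------------------------------------------------------------------
# plain-text config round trip


def save_surrogate_config(model: _Surrogate, path) -> None:
    """Write a ``key = value`` config from which the surrogate rebuilds.

    Randomized grids are re-derived from the stored seed; a regional-sum
    label map is stored as a grayscale PNG next to the config.
    """
    from pdprobe import io as _io

    path = Path(path)
    spec = model.spec
    lines = [f"kind = {spec.kind}", f"seed = {spec.seed}"]
    for key, val in spec.params.items():
        if key == "labels":
            continue
        if np.isscalar(val):
            lines.append(f"{key} = {val!r}")
    if spec.kind == "regional-sum":
        label_file = path.with_suffix(".labels.png")
        _io.write_labels_png(label_file, model.labels)
        lines.append(f"labels = {label_file.name}")
    path.write_text("\n".join(lines) + "\n")


def load_surrogate_config(path) -> _Surrogate:
    """Rebuild a surrogate from :func:`save_surrogate_config` output."""
    from pdprobe import io as _io
    from pdprobe.config import parse_config

    path = Path(path)
    cfg = parse_config(path.read_text())
    kind = str(cfg.pop("kind"))
    seed = int(cfg.pop("seed", 0))
    if "labels" in cfg:
        cfg["labels"] = _io.read_labels_png(path.parent / str(cfg["labels"]))
    return make_surrogate(SurrogateSpec(kind, seed=seed, params=cfg))


def save_weight_grid_csv(model: LinearSurrogate, path) -> None:
    """Flat CSV (row, col, channel, weight) of a linear-family weight grid."""
    w = model.weights
    rows, cols, chs = np.nonzero(np.ones_like(w, dtype=bool))
    with open(path, "w") as fh:
        fh.write("row,col,channel,weight\n")
        for r, c, k in zip(rows, cols, chs):
            fh.write(f"{r},{c},{k},{w[r, c, k]!r}\n")
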