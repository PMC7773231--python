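"""Core data structures and numerics for time-domain FLIM decay analysis.

Time-correlated single-photon counting (TCSPC) yields, per pixel, a histogram
of photon arrival times — the *transient* or *decay curve*.  Every fitter in
this package estimates the parameters of an exponential decay law from such a
histogram.  This module holds the shared vocabulary:

* :class:`TimeGrid`, :class:`DecayCurve`, :class:`FLIMImage`, :class:`IRF` —
  the data containers;
* :class:`DecayModelSpec` — the parameter vector (offset ``Z``, amplitudes
  ``A_i``, lifetimes ``tau_i``, stretch ``h``) all fitters estimate;
* :class:`NoiseModel` and :func:`noise_variance` — the five per-bin variance
  models that weight the chi-squared objective;
* :func:`eval_model`, :func:`convolve_with_irf`, :func:`objective` — the model
  evaluation, instrument-response convolution and fit objectives every fitter
  shares.

Conventions used throughout the package:

* times are in nanoseconds; counts are photons;
* models are evaluated at **bin centers**, with ``t`` restarting at 0 at the
  leading edge of the fit range — this makes RLD, LM and phasor estimates
  mutually consistent and makes noiseless recovery exact;
* fit ranges are half-open ``[start_bin, end_bin)``;
* image axes are ordered ``(time, y, x)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("flimkit")

#: Variance floor for the 'poisson' noise model: below ~15 counts the Gaussian
#: approximation to Poisson statistics breaks down, so the per-bin variance is
#: never taken smaller than this.
POISSON_VARIANCE_FLOOR = 15.0

MODEL_KINDS = ("multi_exp", "stretched_exp")
NOISE_KINDS = ("constant", "given", "gaussian", "poisson", "mle")


class FlimError(Exception):
    """Base class for flimkit errors."""


class InvalidParameterError(FlimError, ValueError):
    """A model/parameter value violates its domain (e.g. tau <= 0)."""


class DataError(FlimError, ValueError):
    """Input data violates a precondition (shape, sign, spacing...)."""


class FitError(FlimError, RuntimeError):
    """A fit could not be carried out (degenerate data, singular matrix)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis of a TCSPC histogram.

    Parameters
    ----------
    n_bins
        Number of time bins (>= 3).
    bin_width_ns
        Width of one bin in nanoseconds (> 0).
    origin_ns
        Time of the leading edge of bin 0 (default 0).
    """

    n_bins: int
    bin_width_ns: float
    origin_ns: float = 0.0

    def __post_init__(self) -> None:
        if int(self.n_bins) != self.n_bins or self.n_bins < 3:
            raise DataError(f"n_bins must be an integer >= 3, got {self.n_bins}")
        if not (self.bin_width_ns > 0):
            raise DataError(f"bin_width_ns must be > 0, got {self.bin_width_ns}")

    @property
    def duration_ns(self) -> float:
        return self.n_bins * self.bin_width_ns

    def bin_centers(self) -> np.ndarray:
        """Absolute time of each bin center."""
        return self.origin_ns + (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    def bin_edges(self) -> np.ndarray:
        return self.origin_ns + np.arange(self.n_bins + 1) * self.bin_width_ns


@dataclass(frozen=True)
class FitRange:
    """Half-open bin interval ``[start_bin, end_bin)`` used for fitting."""

    start_bin: int
    end_bin: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_bin < self.end_bin):
            raise DataError(
                f"need 0 <= start_bin < end_bin, got [{self.start_bin}, {self.end_bin})"
            )

    def validate(self, grid: TimeGrid, n_free: int = 0) -> None:
        if self.end_bin > grid.n_bins:
            raise DataError(
                f"fit range end {self.end_bin} exceeds n_bins {grid.n_bins}"
            )
        if len(self) < 3 + n_free:
            raise DataError(
                f"fit range of {len(self)} bins too short for {n_free} free parameters"
            )

    def __len__(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def slice(self) -> slice:
        return np.s_[self.start_bin:self.end_bin]

    def times(self, grid: TimeGrid) -> np.ndarray:
        """Bin-center times measured from the fit-range start's leading edge."""
        return (np.arange(len(self)) + 0.5) * grid.bin_width_ns

    def duration(self, grid: TimeGrid) -> float:
        return len(self) * grid.bin_width_ns


def full_range(grid: TimeGrid) -> FitRange:
    return FitRange(0, grid.n_bins)


def _as_counts(counts, n_expect: Optional[int] = None, name: str = "counts") -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be 1-D, got shape {arr.shape}")
    if n_expect is not None and arr.size != n_expect:
        raise DataError(f"{name} length {arr.size} != grid n_bins {n_expect}")
    if np.any(arr < 0):
        raise DataError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class DecayCurve:
    """One pixel's photon counts per time bin."""

    grid: TimeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _as_counts(self.counts, self.grid.n_bins))

    def total(self, fit_range: Optional[FitRange] = None) -> float:
        if fit_range is None:
            return float(self.counts.sum())
        return float(self.counts[fit_range.slice].sum())


@dataclass(frozen=True)
class FLIMImage:
    """3-D photon count stack with axes ``(time, y, x)`` sharing one TimeGrid."""

    grid: TimeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 3:
            raise DataError(f"image counts must be 3-D (time, y, x), got {arr.shape}")
        if arr.shape[0] != self.grid.n_bins:
            raise DataError(
                f"time axis length {arr.shape[0]} != grid n_bins {self.grid.n_bins}"
            )
        if np.any(arr < 0):
            raise DataError("image counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (height, width)."""
        return self.counts.shape[1:]

    def pixel(self, y: int, x: int) -> DecayCurve:
        return DecayCurve(self.grid, self.counts[:, y, x])

    def intensity(self, fit_range: Optional[FitRange] = None) -> np.ndarray:
        """Total in-range photons per pixel."""
        sl = slice(None) if fit_range is None else fit_range.slice
        return self.counts[sl].sum(axis=0)


@dataclass(frozen=True)
class IRF:
    """Instrument response function (prompt) on the data's time grid.

    The measured transient is the true decay convolved with the IRF; fitters
    that accept an IRF reconvolve the candidate model with it at every
    iteration.  The IRF is normalized to unit sum before use so that model
    amplitudes keep photon-count units.
    """

    grid: TimeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_counts(self.counts, self.grid.n_bins, "IRF counts")
        if not np.any(arr > 0):
            raise DataError("IRF must have at least one positive entry")
        object.__setattr__(self, "counts", arr)

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class DecayModelSpec:
    """Decay-law parameter vector.

    ``multi_exp``:      y(t) = Z + sum_i A_i * exp(-t / tau_i)
    ``stretched_exp``:  y(t) = Z + A * exp(-(t / tau) ** (1 / h))

    ``t`` is measured from the start of the fit range.  ``Z`` is a constant
    background offset in counts; amplitudes are in counts; lifetimes in ns.
    """

    kind: str
    Z: float
    A: np.ndarray
    tau: np.ndarray
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise InvalidParameterError(f"unknown model kind {self.kind!r}")
        A = np.atleast_1d(np.asarray(self.A, dtype=float))
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if A.shape != tau.shape or A.ndim != 1:
            raise InvalidParameterError("A and tau must be 1-D and the same length")
        if self.kind == "stretched_exp" and A.size != 1:
            raise InvalidParameterError("stretched_exp is single-component")
        if np.any(tau <= 0):
            raise InvalidParameterError(f"lifetimes must be positive, got {tau}")
        if not (self.h > 0):
            raise InvalidParameterError(f"stretch parameter h must be positive, got {self.h}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "Z", float(self.Z))
        object.__setattr__(self, "h", float(self.h))

    @property
    def n_components(self) -> int:
        return self.A.size

    def param_names(self) -> list[str]:
        if self.kind == "stretched_exp":
            return ["Z", "A", "tau", "h"]
        names = ["Z"]
        for i in range(self.n_components):
            names += [f"A{i + 1}", f"tau{i + 1}"]
        return names

    def to_vector(self) -> np.ndarray:
        if self.kind == "stretched_exp":
            return np.array([self.Z, self.A[0], self.tau[0], self.h])
        out = np.empty(1 + 2 * self.n_components)
        out[0] = self.Z
        out[1::2] = self.A
        out[2::2] = self.tau
        return out

    @classmethod
    def from_vector(cls, kind: str, vec: np.ndarray) -> "DecayModelSpec":
        vec = np.asarray(vec, dtype=float)
        if kind == "stretched_exp":
            return cls(kind, Z=vec[0], A=vec[1:2], tau=vec[2:3], h=vec[3])
        return cls(kind, Z=vec[0], A=vec[1::2], tau=vec[2::2])

    @classmethod
    def mono_exp(cls, Z: float, A: float, tau: float) -> "DecayModelSpec":
        return cls("multi_exp", Z=Z, A=[A], tau=[tau])


@dataclass(frozen=True)
class NoiseModel:
    """Per-bin variance model weighting the least-squares objective.

    kind
        * ``constant`` — one supplied variance ``sigma2`` for every bin;
        * ``given``    — per-bin variances supplied in ``variances``;
        * ``gaussian`` — variance equal to the observed count (floored at 1);
        * ``poisson``  — variance equal to the observed count with a lower
          limit of 15, the point where the Gaussian approximation to Poisson
          counting noise breaks down;
        * ``mle``      — no per-bin variances; the fit minimizes the Poisson
          deviance instead of a weighted chi-squared.
    """

    kind: str = "poisson"
    sigma2: Optional[float] = None
    variances: Optional[np.ndarray] = None
    poisson_floor: float = POISSON_VARIANCE_FLOOR

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.kind == "constant":
            if self.sigma2 is None or not (self.sigma2 > 0):
                raise InvalidParameterError("constant noise requires sigma2 > 0")
        if self.kind == "given":
            if self.variances is None:
                raise InvalidParameterError("given noise requires a variances array")
            var = np.asarray(self.variances, dtype=float)
            if np.any(var <= 0):
                raise InvalidParameterError("supplied variances must be positive")
            object.__setattr__(self, "variances", var)
        if self.poisson_floor != POISSON_VARIANCE_FLOOR:
            raise InvalidParameterError(
                f"poisson_floor is fixed at {POISSON_VARIANCE_FLOOR}"
            )


# ---------------------------------------------------------------------------
# Model evaluation and convolution
# ---------------------------------------------------------------------------

def eval_model(
    spec: DecayModelSpec,
    grid: TimeGrid,
    fit_range: Optional[FitRange] = None,
) -> np.ndarray:
    """Evaluate the decay law at each bin center within the fit range.

    ``t`` is measured from the fit-range start's leading edge to the bin
    center, so the first bin sees ``t = bin_width / 2``.
    """
    if fit_range is None:
        fit_range = full_range(grid)
    fit_range.validate(grid)
    t = fit_range.times(grid)
    return eval_model_at(spec, t)


def eval_model_at(spec: DecayModelSpec, t: np.ndarray) -> np.ndarray:
    """Evaluate the decay law at arbitrary times ``t`` (ns, from range start)."""
    t = np.asarray(t, dtype=float)
    if spec.kind == "stretched_exp":
        return spec.Z + spec.A[0] * np.exp(-np.power(t / spec.tau[0], 1.0 / spec.h))
    return spec.Z + np.exp(-t[..., None] / spec.tau) @ spec.A


def convolve_with_irf(model: np.ndarray, irf: IRF | np.ndarray) -> np.ndarray:
    """Causal discrete convolution of a model curve with the (normalized) IRF.

    ``c_j = sum_{k <= j} irf_k * model_{j-k}``, truncated to the model's
    length.  The constant offset ``Z`` must be excluded by the caller and
    added back afterwards — convolving a constant with a unit-sum kernel
    would smear it across the leading bins.
    """
    model = np.asarray(model, dtype=float)
    if isinstance(irf, IRF):
        kernel = irf.normalized()
    else:
        kernel = np.asarray(irf, dtype=float)
        total = kernel.sum()
        if not np.any(kernel > 0) or total <= 0:
            raise DataError("IRF must have positive total intensity")
        kernel = kernel / total
    if model.size == 0:
        return model.copy()
    return np.convolve(kernel, model)[: model.size]


# ---------------------------------------------------------------------------
# Noise variances and objectives
# ---------------------------------------------------------------------------

def noise_variance(
    noise: NoiseModel,
    data: np.ndarray,
    model: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-bin variance under the chosen noise model.

    Not defined for the ``mle`` kind, which replaces weighted least squares
    by the Poisson deviance (see :func:`objective`).
    """
    data = np.asarray(data, dtype=float)
    if model is not None and np.asarray(model).shape != data.shape:
        raise DataError("data and model must have the same length")
    if noise.kind == "constant":
        return np.full(data.shape, float(noise.sigma2))
    if noise.kind == "given":
        if noise.variances.shape != data.shape:
            raise DataError(
                f"given variances length {noise.variances.size} != data length {data.size}"
            )
        return noise.variances.copy()
    if noise.kind == "gaussian":
        return np.maximum(data, 1.0)
    if noise.kind == "poisson":
        return np.maximum(data, noise.poisson_floor)
    raise InvalidParameterError(
        "the 'mle' noise model has no per-bin variances; it uses the Poisson deviance"
    )


def poisson_deviance(y: np.ndarray, f: np.ndarray) -> float:
    """Poisson deviance 2*sum[f - y + y*ln(y/f)]; the y=0 term is 2*f.

    Equals (twice) the log-likelihood-ratio against the saturated model; this
    is the 'mle' fit objective, >= 0 with equality iff f == y.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise InvalidParameterError("mle objective requires a strictly positive model")
    terms = f - y
    pos = y > 0
    terms[pos] += y[pos] * np.log(y[pos] / f[pos])
    return float(2.0 * terms.sum())


def objective(
    data: DecayCurve | np.ndarray,
    model: np.ndarray,
    noise: NoiseModel,
    fit_range: Optional[FitRange] = None,
) -> float:
    """Fit objective: weighted chi-squared, or Poisson deviance for ``mle``.

    ``model`` must already be evaluated on the fit range.
    """
    if isinstance(data, DecayCurve):
        if fit_range is None:
            fit_range = full_range(data.grid)
        y = data.counts[fit_range.slice]
    else:
        y = np.asarray(data, dtype=float)
        if fit_range is not None:
            y = y[fit_range.slice]
    model = np.asarray(model, dtype=float)
    if model.shape != y.shape:
        raise DataError(
            f"model length {model.size} does not match fit-range length {y.size}"
        )
    if noise.kind == "mle":
        return poisson_deviance(y, model)
    var = noise_variance(noise, y, model)
    return float(np.sum((y - model) ** 2 / var))


def reduced_chi_squared(value: float, n_points: int, n_free: int) -> float:
    """Objective divided by degrees of freedom (n_points - n_free)."""
    dof = n_points - n_free
    if dof <= 0:
        return float("nan")
    return value / dof


# ---------------------------------------------------------------------------
# Shared fit-result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of fitting one transient.

    ``std_errors`` follow the order of the free parameters in
    ``spec.param_names()``; they are curvature-matrix (alpha-matrix) errors
    scaled by sqrt(reduced chi-squared) for weighted-least-squares noise
    models (``std_errors_raw`` keeps the unscaled values).
    """

    spec: DecayModelSpec
    reduced_chisq: float
    fitted_curve: np.ndarray
    residuals: np.ndarray
    iterations: int = 0
    converged: bool = True
    std_errors: Optional[np.ndarray] = None
    std_errors_raw: Optional[np.ndarray] = None
    free_names: Optional[list[str]] = None
    objective_value: float = float("nan")
    extra: dict = field(default_factory=dict)

    @property
    def tau(self) -> np.ndarray:
        return self.spec.tau

    def __repr__(self) -> str:  # compact, for CLI/log output
        taus = ", ".join(f"{t:.4g}" for t in self.spec.tau)
        return (
            f"FitResult(kind={self.spec.kind}, Z={self.spec.Z:.4g}, "
            f"A={np.array2string(self.spec.A, precision=4)}, tau=[{taus}] ns, "
            f"red_chisq={self.reduced_chisq:.4g}, converged={self.converged})"
        )
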