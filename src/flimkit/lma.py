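"""Levenberg-Marquardt decay fitting with optional IRF reconvolution.

Minimizes the noise-model-weighted chi-squared (or, for the ``mle`` noise
model, the Poisson deviance via Fisher scoring) over the free parameters of a
multi- or stretched-exponential decay.  Supports parameter fixing, box
restraints (projection after each accepted step), iterative reconvolution
with an instrument response function, and alpha-matrix (curvature) standard
errors.

Damping schedule: lambda starts at 1e-3, x10 on a rejected step, /10 on an
accepted step; convergence is declared when the relative objective decrease
of an accepted step falls below ``tolerance`` or lambda exceeds 1e10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    DecayCurve,
    DecayModelSpec,
    FitError,
    FitRange,
    FitResult,
    InvalidParameterError,
    IRF,
    NoiseModel,
    full_range,
    noise_variance,
    poisson_deviance,
    reduced_chi_squared,
)
from .rld import fit_rld

_LAMBDA_INIT = 1e-3
_LAMBDA_MAX = 1e10


@dataclass
class FitConfig:
    """Configuration of a Levenberg-Marquardt (or global) fit.

    ``fixed`` lists parameter names (``Z``, ``A1``, ``tau1``, ..., ``h``)
    held at their initial values; ``fixed_values`` fixes parameters at the
    given values regardless of the initial estimate; ``restraints`` maps
    parameter names to ``(lower, upper)`` boxes enforced by projection.
    """

    fit_range: Optional[FitRange] = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    fixed: Sequence[str] = ()
    fixed_values: Mapping[str, float] = field(default_factory=dict)
    restraints: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    max_iterations: int = 100
    tolerance: float = 1e-6
    initial: Optional[DecayModelSpec] = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.restraints.items():
            if not lo < hi:
                raise InvalidParameterError(
                    f"restraint for {name} must have lower < upper, got ({lo}, {hi})"
                )
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")


def default_initial_estimate(
    decay: DecayCurve,
    fit_range: Optional[FitRange] = None,
    n_components: int = 1,
    kind: str = "multi_exp",
) -> DecayModelSpec:
    """Starting parameters for the LM fit.

    One component: the RLD closed-form estimate.  k components: the RLD
    lifetime split geometrically over (tau/2, 2*tau) with the amplitude
    divided equally; Z from RLD.  If RLD fails (flat or rising transient) a
    heuristic fallback is used: Z = min(y), A = max(y) - min(y) (at least 1),
    tau = a quarter of the fit-range duration.
    """
    grid = decay.grid
    if fit_range is None:
        fit_range = full_range(grid)
    try:
        base = fit_rld(decay, fit_range).spec
        Z, A, tau = base.Z, float(base.A[0]), float(base.tau[0])
    except FitError:
        y = decay.counts[fit_range.slice]
        Z = float(y.min())
        A = max(float(y.max() - y.min()), 1.0)
        tau = 0.25 * fit_range.duration(grid)
    if kind == "stretched_exp":
        return DecayModelSpec("stretched_exp", Z=Z, A=[A], tau=[tau], h=1.0)
    if n_components == 1:
        return DecayModelSpec.mono_exp(Z=Z, A=A, tau=tau)
    taus = np.geomspace(tau / 2.0, 2.0 * tau, n_components)
    amps = np.full(n_components, A / n_components)
    return DecayModelSpec("multi_exp", Z=Z, A=amps, tau=taus)


def estimate_errors(alpha: np.ndarray, reduced_chisq: float = 1.0) -> np.ndarray:
    """Standard errors from the curvature (alpha) matrix at the optimum.

    ``std_error_k = sqrt((alpha^-1)_kk * reduced_chisq)``; pass
    ``reduced_chisq = 1`` for unscaled (raw) errors.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2 or alpha.shape[0] != alpha.shape[1]:
        raise InvalidParameterError("alpha must be a square matrix")
    try:
        inv = np.linalg.inv(alpha)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"curvature matrix is singular: {exc}") from exc
    diag = np.diag(inv)
    if np.any(diag < 0):
        raise FitError("curvature matrix is not positive definite")
    return np.sqrt(diag * max(reduced_chisq, 0.0))


class _ModelFunction:
    """Packed-vector model evaluation and Jacobian over a fit range."""

    def __init__(self, kind: str, n_components: int, t: np.ndarray,
                 irf_kernel: Optional[np.ndarray]):
        self.kind = kind
        self.k = n_components
        self.t = t
        self.irf_kernel = irf_kernel

    def _conv(self, curve: np.ndarray) -> np.ndarray:
        if self.irf_kernel is None:
            return curve
        return np.convolve(self.irf_kernel, curve)[: curve.size]

    def valid(self, p: np.ndarray) -> bool:
        if self.kind == "stretched_exp":
            return p[2] > 0 and p[3] > 0
        return bool(np.all(p[2::2] > 0))

    def __call__(self, p: np.ndarray) -> Optional[np.ndarray]:
        if not self.valid(p) or not np.all(np.isfinite(p)):
            return None
        if self.kind == "stretched_exp":
            Z, A, tau, h = p
            d = A * np.exp(-np.power(self.t / tau, 1.0 / h))
        else:
            Z = p[0]
            E = np.exp(-self.t[:, None] / p[2::2])
            d = E @ p[1::2]
        return Z + self._conv(d)

    def jacobian(self, p: np.ndarray) -> np.ndarray:
        n = self.t.size
        if self.kind == "stretched_exp":
            # central finite differences, 1e-6 relative step
            J = np.empty((n, 4))
            J[:, 0] = 1.0
            for j in (1, 2, 3):
                step = 1e-6 * max(abs(p[j]), 1e-3)
                hi, lo = p.copy(), p.copy()
                hi[j] += step
                lo[j] -= step
                fh, fl = self(hi), self(lo)
                if fh is None or fl is None:
                    raise FitError("finite-difference step left the parameter domain")
                J[:, j] = (fh - fl) / (2 * step)
            return J
        taus = p[2::2]
        amps = p[1::2]
        E = np.exp(-self.t[:, None] / taus)
        J = np.empty((n, 1 + 2 * self.k))
        J[:, 0] = 1.0
        for i in range(self.k):
            J[:, 1 + 2 * i] = self._conv(E[:, i])
            J[:, 2 + 2 * i] = self._conv(amps[i] * self.t / taus[i] ** 2 * E[:, i])
        return J


def _clamp(p: np.ndarray, boxes: list[tuple[int, float, float]]) -> np.ndarray:
    for idx, lo, hi in boxes:
        p[idx] = min(max(p[idx], lo), hi)
    return p


def fit_lma(
    decay: DecayCurve,
    config: Optional[FitConfig] = None,
    irf: Optional[IRF] = None,
    n_components: int = 1,
    kind: str = "multi_exp",
) -> FitResult:
    """Levenberg-Marquardt fit of one transient.

    With an IRF, the candidate model (minus the offset Z) is convolved with
    the normalized IRF at every iteration before comparison with the data
    (iterative reconvolution).  Non-convergence after ``max_iterations`` is
    reported via ``converged=False``, not an exception; a singular curvature
    matrix raises :class:`FitError`.
    """
    if config is None:
        config = FitConfig()
    grid = decay.grid
    fr = config.fit_range or full_range(grid)

    init = config.initial or default_initial_estimate(decay, fr, n_components, kind)
    kind = init.kind
    names = init.param_names()
    if config.fixed_values:
        vec = init.to_vector()
        for nm, val in config.fixed_values.items():
            if nm not in names:
                raise InvalidParameterError(f"unknown parameter name {nm!r} for {kind}")
            vec[names.index(nm)] = val
        init = DecayModelSpec.from_vector(kind, vec)
    all_fixed = set(config.fixed) | set(config.fixed_values)
    free = np.array([nm not in all_fixed for nm in names])
    if not free.any():
        raise InvalidParameterError("at least one parameter must be free")
    n_free = int(free.sum())
    fr.validate(grid, n_free)

    for nm in list(all_fixed) + list(config.restraints):
        if nm not in names:
            raise InvalidParameterError(f"unknown parameter name {nm!r} for {kind}")
    boxes = [
        (names.index(nm), lo, hi) for nm, (lo, hi) in config.restraints.items()
    ]

    y = decay.counts[fr.slice]
    t = fr.times(grid)
    kernel = None
    if irf is not None:
        if irf.grid.n_bins != grid.n_bins or irf.grid.bin_width_ns != grid.bin_width_ns:
            raise InvalidParameterError("IRF must share the data's time grid")
        win = irf.counts[fr.slice]
        if not np.any(win > 0):
            raise InvalidParameterError("IRF is zero inside the fit range")
        kernel = win / win.sum()
    model = _ModelFunction(kind, init.n_components, t, kernel)

    mle = config.noise.kind == "mle"
    w_fixed = None if mle else 1.0 / noise_variance(config.noise, y)

    def obj_of(f: np.ndarray) -> float:
        if mle:
            return poisson_deviance(y, f)
        return float(np.sum(w_fixed * (y - f) ** 2))

    p = _clamp(init.to_vector(), boxes)
    f = model(p)
    if f is None:
        raise InvalidParameterError("initial parameters are outside the model domain")
    if mle and f.min() <= 0:
        # lift the curve into positivity; the optimizer refines Z from there
        p[0] += 1e-6 + max(0.0, -f.min())
        f = model(p)
    obj = obj_of(f)

    lam = _LAMBDA_INIT
    converged = False
    iterations = 0
    free_idx = np.flatnonzero(free)

    for iterations in range(1, config.max_iterations + 1):
        J = model.jacobian(p)[:, free_idx]
        w_it = (1.0 / f) if mle else w_fixed
        r = y - f
        alpha = (J * w_it[:, None]).T @ J
        beta = J.T @ (w_it * r)
        diag = np.diag(alpha).copy()
        if not np.all(np.isfinite(alpha)) or np.any(diag <= 0):
            raise FitError(
                "singular curvature matrix (a free parameter has no effect on the "
                f"model); diag(alpha) = {diag}"
            )
        accepted = False
        while True:
            try:
                delta = np.linalg.solve(alpha + lam * np.diag(diag), beta)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"singular damped curvature matrix: {exc}") from exc
            p_trial = p.copy()
            p_trial[free_idx] += delta
            _clamp(p_trial, boxes)
            f_trial = model(p_trial)
            ok = (
                f_trial is not None
                and np.all(np.isfinite(f_trial))
                and not (mle and f_trial.min() <= 0)
            )
            obj_trial = obj_of(f_trial) if ok else np.inf
            if ok and obj_trial <= obj:
                improvement = obj - obj_trial
                p, f, obj = p_trial, f_trial, obj_trial
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                if improvement < config.tolerance * max(obj_trial, 1e-12):
                    converged = True
                break
            lam *= 10.0
            if lam > _LAMBDA_MAX:
                converged = True  # stalled at a (local) minimum
                break
        if converged or not accepted:
            break

    spec = DecayModelSpec.from_vector(kind, p)
    rchisq = reduced_chi_squared(obj, y.size, n_free)

    # undamped curvature at the optimum for the error estimates
    J = model.jacobian(p)[:, free_idx]
    w_it = (1.0 / f) if mle else w_fixed
    alpha = (J * w_it[:, None]).T @ J
    try:
        raw = estimate_errors(alpha, 1.0)
        scaled = raw if mle else raw * np.sqrt(max(rchisq, 0.0))
    except FitError:
        raw = scaled = np.full(n_free, np.nan)

    return FitResult(
        spec=spec,
        reduced_chisq=rchisq,
        fitted_curve=f,
        residuals=y - f,
        iterations=iterations,
        converged=converged,
        std_errors=scaled,
        std_errors_raw=raw,
        free_names=[nm for nm in names if nm not in all_fixed],
        objective_value=obj,
    )
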