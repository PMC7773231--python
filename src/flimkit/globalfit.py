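"""Global analysis: lifetimes shared across pixels, amplitudes/offset local.

Uses variable projection: for any candidate set of shared lifetimes the
per-pixel offset and amplitudes are an exact weighted linear least-squares
solve against the basis {1, exp(-t/tau_i)}, so the outer optimization runs
only over the k shared lifetimes.  The outer loop is Levenberg-Marquardt in
log(tau) (which keeps lifetimes positive) with a finite-difference Jacobian
of the stacked weighted residuals; it is initialized from a per-image LM fit
of the summed transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    DecayCurve,
    DecayModelSpec,
    FitError,
    FitRange,
    FLIMImage,
    InvalidParameterError,
    NoiseModel,
    full_range,
    noise_variance,
)
from .lma import FitConfig, default_initial_estimate, fit_lma

_LAMBDA_MAX = 1e10


@dataclass
class GlobalFitResult:
    """Shared lifetimes plus per-pixel parameter maps."""

    global_tau: np.ndarray
    maps: dict[str, np.ndarray]
    total_chisq: float
    iterations: int
    converged: bool
    mask: np.ndarray = field(default=None)  # pixels that entered the fit

    @property
    def n_components(self) -> int:
        return self.global_tau.size


def _basis(t: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Design matrix columns {1, exp(-t/tau_i)}."""
    B = np.empty((t.size, tau.size + 1))
    B[:, 0] = 1.0
    B[:, 1:] = np.exp(-t[:, None] / tau[None, :])
    return B


def _check_distinct(tau: np.ndarray) -> None:
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise InvalidParameterError(f"lifetimes must be positive, got {tau}")
    ts = np.sort(tau)
    if tau.size > 1 and np.any(np.diff(ts) < 1e-9 * ts[:-1]):
        raise FitError(f"duplicate lifetimes {tau} make the amplitude basis collinear")


def solve_linear_amplitudes(
    decay: DecayCurve,
    tau: np.ndarray,
    noise: Optional[NoiseModel] = None,
    fit_range: Optional[FitRange] = None,
) -> tuple[float, np.ndarray]:
    """Exact weighted linear LS for (Z, A_1..A_k) at fixed lifetimes.

    Solves the normal equations for the basis {1, exp(-t/tau_i)}; raises on a
    collinear basis (duplicate lifetimes).
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    _check_distinct(tau)
    grid = decay.grid
    if fit_range is None:
        fit_range = full_range(grid)
    fit_range.validate(grid, tau.size + 1)
    if noise is None:
        noise = NoiseModel()
    y = decay.counts[fit_range.slice]
    w = 1.0 / noise_variance(noise, y)
    B = _basis(fit_range.times(grid), tau)
    G = (B * w[:, None]).T @ B
    rhs = B.T @ (w * y)
    try:
        coef = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"amplitude normal equations are singular: {exc}") from exc
    return float(coef[0]), coef[1:]


class _ImageProblem:
    """Vectorized per-pixel weighted linear solves for the whole image."""

    def __init__(self, Y: np.ndarray, W: np.ndarray, t: np.ndarray):
        self.Y = Y          # (P, n)
        self.W = W          # (P, n)
        self.t = t
        self.wyy = np.einsum("pi,pi,pi->p", W, Y, Y)  # sum w*y^2 per pixel

    def solve(self, tau: np.ndarray):
        """Return (coefs (P, k+1), chisq (P,)) at fixed lifetimes."""
        B = _basis(self.t, tau)                        # (n, q)
        q = B.shape[1]
        M = (B[:, :, None] * B[:, None, :]).reshape(self.t.size, q * q)
        G = (self.W @ M).reshape(-1, q, q)             # (P, q, q)
        R = (self.W * self.Y) @ B                      # (P, q)
        try:
            coefs = np.linalg.solve(G, R[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise FitError(f"amplitude solve failed at tau={tau}: {exc}") from exc
        chisq = self.wyy - 2 * np.einsum("pq,pq->p", coefs, R) + np.einsum(
            "pq,pqr,pr->p", coefs, G, coefs
        )
        return coefs, np.maximum(chisq, 0.0)

    def residuals(self, tau: np.ndarray) -> np.ndarray:
        """Stacked weighted residuals sqrt(w)*(y - B c), flattened."""
        B = _basis(self.t, tau)
        coefs, _ = self.solve(tau)
        fit = coefs @ B.T
        return (np.sqrt(self.W) * (self.Y - fit)).ravel()


def fit_global(
    image: FLIMImage,
    n_components: int = 2,
    config: Optional[FitConfig] = None,
    initial_tau: Optional[np.ndarray] = None,
    intensity_threshold: float = 0.0,
    max_outer: Optional[int] = None,
) -> GlobalFitResult:
    """Fit shared lifetimes to all pixels above the intensity threshold.

    ``max_outer = 0`` skips the outer optimization and returns the amplitude
    maps at ``initial_tau`` (useful for fitting with lifetimes frozen at
    known values).
    """
    if config is None:
        config = FitConfig()
    if config.noise.kind == "mle":
        raise InvalidParameterError(
            "global analysis uses weighted least squares; choose a variance-based "
            "noise model"
        )
    grid = image.grid
    fr = config.fit_range or full_range(grid)
    fr.validate(grid, n_components + 1)
    if max_outer is None:
        max_outer = config.max_iterations

    intensity = image.intensity(fr)
    mask = intensity >= intensity_threshold
    P = int(mask.sum())
    if P < 2:
        raise FitError(f"global fit needs >= 2 pixels above threshold, got {P}")

    n = len(fr)
    Y = image.counts[fr.slice].reshape(n, -1).T[mask.ravel()]   # (P, n)
    if config.noise.kind == "constant":
        W = np.full_like(Y, 1.0 / config.noise.sigma2)
    elif config.noise.kind == "given":
        W = np.broadcast_to(1.0 / config.noise.variances, Y.shape).copy()
    elif config.noise.kind == "gaussian":
        W = 1.0 / np.maximum(Y, 1.0)
    else:  # poisson
        W = 1.0 / np.maximum(Y, config.noise.poisson_floor)
    t = fr.times(grid)
    problem = _ImageProblem(Y, W, t)

    # --- initial shared lifetimes: LM fit of the image-summed transient
    if initial_tau is not None:
        tau = np.sort(np.atleast_1d(np.asarray(initial_tau, dtype=float)))
        _check_distinct(tau)
    else:
        summed = DecayCurve(grid, image.counts.reshape(grid.n_bins, -1).sum(axis=1))
        sum_cfg = FitConfig(fit_range=fr, noise=config.noise,
                            max_iterations=config.max_iterations,
                            tolerance=config.tolerance)
        try:
            res = fit_lma(summed, sum_cfg, n_components=n_components)
            tau = np.sort(res.spec.tau)
        except FitError:
            init = default_initial_estimate(summed, fr, n_components)
            tau = np.sort(init.tau)
        _check_distinct(tau)

    # --- outer LM over theta = log(tau)
    theta = np.log(tau)
    converged = max_outer == 0
    iterations = 0

    def total_obj(th: np.ndarray) -> float:
        _, chisq = problem.solve(np.exp(th))
        return float(chisq.sum())

    if max_outer > 0:
        r = problem.residuals(np.exp(theta))
        obj = float(r @ r)
        lam = 1e-3
        k = theta.size
        for iterations in range(1, max_outer + 1):
            # central-difference Jacobian of the stacked residuals
            J = np.empty((r.size, k))
            for j in range(k):
                step = 1e-5
                hi, lo = theta.copy(), theta.copy()
                hi[j] += step
                lo[j] -= step
                J[:, j] = (problem.residuals(np.exp(hi)) - problem.residuals(np.exp(lo))) / (2 * step)
            alpha = J.T @ J
            beta = -(J.T @ r)   # J is d(residual)/d(theta)
            diag = np.diag(alpha).copy()
            if np.any(diag <= 0) or not np.all(np.isfinite(alpha)):
                raise FitError("singular outer curvature matrix in global fit")
            accepted = False
            while True:
                delta = np.linalg.solve(alpha + lam * np.diag(diag), beta)
                th_trial = theta + delta
                try:
                    r_trial = problem.residuals(np.exp(th_trial))
                    obj_trial = float(r_trial @ r_trial)
                except FitError:
                    obj_trial = np.inf
                if np.isfinite(obj_trial) and obj_trial <= obj:
                    improvement = obj - obj_trial
                    theta, r, obj = th_trial, r_trial, obj_trial
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    if improvement < config.tolerance * max(obj_trial, 1e-12):
                        converged = True
                    break
                lam *= 10.0
                if lam > _LAMBDA_MAX:
                    converged = True
                    break
            if converged or not accepted:
                break

    tau = np.exp(theta)
    order = np.argsort(tau)
    tau = tau[order]

    coefs, chisq = problem.solve(tau)
    bad = ~np.isfinite(chisq)
    if bad.sum() > 0.5 * P:
        raise FitError("amplitude solve failed on more than half of the pixels")

    H, W_img = image.shape
    def to_map(values: np.ndarray) -> np.ndarray:
        out = np.full(H * W_img, np.nan)
        out[mask.ravel()] = values
        return out.reshape(H, W_img)

    dof = n - (n_components + 1)
    maps = {"Z": to_map(coefs[:, 0])}
    for i, comp in enumerate(order):
        maps[f"A{i + 1}"] = to_map(coefs[:, 1 + comp])
    maps["chisq_reduced"] = to_map(chisq / dof if dof > 0 else np.nan)
    for i in range(n_components):
        maps[f"tau{i + 1}"] = to_map(np.full(P, tau[i]))

    return GlobalFitResult(
        global_tau=tau,
        maps=maps,
        total_chisq=float(chisq.sum()),
        iterations=iterations,
        converged=converged,
        mask=mask,
    )
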