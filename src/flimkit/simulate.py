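"""Seeded synthetic TCSPC data generators.

These generators reproduce the validation conditions used throughout the
package's test suite: a one-component lifetime sweep (32 levels from 0.2 to
6.0 ns inside a 10 ns window), a two-component mixture image (0.4 / 2.1 ns
with a linear species-fraction gradient, 128x128 pixels) emulating NAD(P)H /
FAD autofluorescence, and binomial photon thinning for low-light variants.

Photon statistics are Poisson per bin; every generator is a pure function of
its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    DataError,
    DecayCurve,
    DecayModelSpec,
    FLIMImage,
    IRF,
    TimeGrid,
    convolve_with_irf,
    eval_model,
)

#: Default TCSPC acquisition window: 256 bins spanning 10 ns.
DEFAULT_GRID = TimeGrid(n_bins=256, bin_width_ns=10.0 / 256)

#: Default photon budget per pixel/transient.
DEFAULT_PHOTONS = 5000.0


@dataclass
class SimulationTruth:
    """Ground truth for a simulated image.

    ``tau`` and ``amplitude`` have shape ``(n_components, H, W)``; ``z`` and
    ``total_photons`` have shape ``(H, W)``.  ``amplitude`` holds the true
    pre-Poisson amplitudes in counts (same scale as the simulated curves).
    """

    tau: np.ndarray
    amplitude: np.ndarray
    z: np.ndarray
    total_photons: np.ndarray
    seed: int
    photon_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.tau.shape != self.amplitude.shape:
            raise DataError("tau and amplitude maps must share a shape")
        if self.tau.shape[1:] != self.z.shape or self.z.shape != self.total_photons.shape:
            raise DataError("truth map shapes disagree")
        if not (0 < self.photon_fraction <= 1):
            raise DataError("photon_fraction must be in (0, 1]")

    @property
    def n_components(self) -> int:
        return self.tau.shape[0]

    def fraction_of(self, component: int = 0) -> np.ndarray:
        """Amplitude fraction A_i / sum(A) per pixel."""
        total = self.amplitude.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.amplitude[component] / total

    def spec_at(self, y: int, x: int) -> DecayModelSpec:
        return DecayModelSpec(
            "multi_exp", Z=self.z[y, x], A=self.amplitude[:, y, x], tau=self.tau[:, y, x]
        )


def _expected_curve(
    spec: DecayModelSpec,
    grid: TimeGrid,
    total_photons: float,
    irf: Optional[IRF],
) -> np.ndarray:
    curve = eval_model(spec, grid)
    if irf is not None:
        curve = convolve_with_irf(curve - spec.Z, irf) + spec.Z
    s = curve.sum()
    if s <= 0:
        raise DataError("model curve has non-positive total intensity")
    return curve * (total_photons / s)


def simulate_transient(
    spec: DecayModelSpec,
    grid: TimeGrid = DEFAULT_GRID,
    total_photons: float = DEFAULT_PHOTONS,
    seed: int = 0,
    irf: Optional[IRF] = None,
    poisson: bool = True,
) -> DecayCurve:
    """Simulate one transient with Poisson photon statistics.

    The expected curve is the decay law at bin centers (IRF-convolved if an
    IRF is given), scaled so its sum equals ``total_photons``; counts are then
    drawn independently Poisson per bin.  With ``poisson=False`` the noiseless
    expected curve is returned (``total_photons = 0`` is then allowed and
    yields the all-zero curve).
    """
    if total_photons < 0 or (total_photons == 0 and poisson):
        raise DataError(f"total_photons must be positive, got {total_photons}")
    if total_photons == 0:
        return DecayCurve(grid, np.zeros(grid.n_bins))
    expected = _expected_curve(spec, grid, total_photons, irf)
    if not poisson:
        return DecayCurve(grid, expected)
    rng = np.random.default_rng(seed)
    return DecayCurve(grid, rng.poisson(expected).astype(float))


def simulate_onecomp_image(
    tau_min: float = 0.2,
    tau_max: float = 6.0,
    n_levels: int = 32,
    grid: TimeGrid = DEFAULT_GRID,
    photons_per_pixel: float = DEFAULT_PHOTONS,
    seed: int = 0,
    block_shape: tuple[int, int] = (8, 8),
    n_block_cols: int = 8,
    poisson: bool = True,
) -> tuple[FLIMImage, SimulationTruth]:
    """One-component lifetime sweep image.

    ``n_levels`` evenly spaced true lifetimes between ``tau_min`` and
    ``tau_max`` (default 32 levels, 0.2-6.0 ns on a 10 ns window), arranged as
    equal rectangular blocks of ``block_shape`` pixels in row-major order on a
    grid of ``n_block_cols`` block columns.  Z = 0 everywhere.
    """
    if n_levels < 2:
        raise DataError("n_levels must be >= 2")
    if not (tau_max < grid.duration_ns):
        raise DataError(
            f"tau_max {tau_max} must fit inside the {grid.duration_ns} ns window"
        )
    if n_levels % n_block_cols:
        raise DataError("n_levels must be divisible by n_block_cols")
    taus = np.linspace(tau_min, tau_max, n_levels)
    bh, bw = block_shape
    n_block_rows = n_levels // n_block_cols
    H, W = n_block_rows * bh, n_block_cols * bw

    tau_map = np.repeat(
        np.repeat(taus.reshape(n_block_rows, n_block_cols), bh, axis=0), bw, axis=1
    )
    stack = np.empty((grid.n_bins, H, W))
    amp_map = np.empty((H, W))
    t = (np.arange(grid.n_bins) + 0.5) * grid.bin_width_ns
    # expected curve per level, broadcast to the block's pixels
    decay = np.exp(-t[:, None] / taus[None, :])        # (n_bins, n_levels)
    scale = photons_per_pixel / decay.sum(axis=0)      # amplitude per level
    rng = np.random.default_rng(seed)
    level_of_pixel = np.repeat(
        np.repeat(
            np.arange(n_levels).reshape(n_block_rows, n_block_cols), bh, axis=0
        ),
        bw,
        axis=1,
    )
    expected = decay[:, level_of_pixel] * scale[level_of_pixel]
    stack = rng.poisson(expected).astype(float) if poisson else expected
    amp_map = scale[level_of_pixel]

    truth = SimulationTruth(
        tau=tau_map[None],
        amplitude=amp_map[None],
        z=np.zeros((H, W)),
        total_photons=np.full((H, W), float(photons_per_pixel)),
        seed=seed,
    )
    return FLIMImage(grid, stack), truth


def simulate_twocomp_image(
    tau: tuple[float, float] = (0.4, 2.1),
    size: tuple[int, int] = (128, 128),
    grid: TimeGrid = DEFAULT_GRID,
    photons_per_pixel: float = DEFAULT_PHOTONS,
    seed: int = 0,
    poisson: bool = True,
) -> tuple[FLIMImage, SimulationTruth]:
    """Two-component mixture image with a linear species-fraction gradient.

    Species A (``tau[0]``) and species B (``tau[1]``) are mixed with an
    amplitude fraction of species A that decreases linearly in (x + y) from 1
    at the top-left pixel to 0 at the bottom-right pixel, emulating the
    NAD(P)H / FAD free-bound contrast of autofluorescence FLIM.  Every
    pixel's expected curve is scaled to ``photons_per_pixel`` total photons.
    """
    tau_a, tau_b = float(tau[0]), float(tau[1])
    if tau_a == tau_b:
        raise DataError("the two component lifetimes must be distinct")
    H, W = size
    if H < 2 or W < 2:
        raise DataError("image must be at least 2x2")
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    frac_a = 1.0 - (xx + yy) / float((H - 1) + (W - 1))   # 1 at TL, 0 at BR

    t = (np.arange(grid.n_bins) + 0.5) * grid.bin_width_ns
    da = np.exp(-t / tau_a)
    db = np.exp(-t / tau_b)
    # amplitude fractions frac_a / (1-frac_a); scale each pixel to the budget
    raw_sum = frac_a * da.sum() + (1 - frac_a) * db.sum()
    scale = photons_per_pixel / raw_sum
    A1 = frac_a * scale
    A2 = (1 - frac_a) * scale
    expected = da[:, None, None] * A1[None] + db[:, None, None] * A2[None]
    rng = np.random.default_rng(seed)
    stack = rng.poisson(expected).astype(float) if poisson else expected

    truth = SimulationTruth(
        tau=np.stack([np.full((H, W), tau_a), np.full((H, W), tau_b)]),
        amplitude=np.stack([A1, A2]),
        z=np.zeros((H, W)),
        total_photons=np.full((H, W), float(photons_per_pixel)),
        seed=seed,
    )
    return FLIMImage(grid, stack), truth


def thin_photons(
    data: DecayCurve | FLIMImage,
    fraction: float,
    seed: int = 0,
):
    """Binomially thin integer photon counts: keep each photon w.p. ``fraction``.

    Thinning a Poisson(mu) count gives Poisson(fraction * mu), so this turns a
    clean simulated dataset into its low-light counterpart.  ``fraction = 1``
    returns the input unchanged.
    """
    if not (0 < fraction <= 1):
        raise DataError(f"fraction must be in (0, 1], got {fraction}")
    counts = data.counts
    if np.any(counts != np.round(counts)):
        raise DataError("thinning requires integer photon counts")
    if fraction == 1.0:
        return data
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts.astype(np.int64), fraction).astype(float)
    if isinstance(data, FLIMImage):
        return FLIMImage(data.grid, thinned)
    return DecayCurve(data.grid, thinned)


def photon_fraction_ladder(
    data: DecayCurve | FLIMImage,
    seed: int = 0,
) -> dict[float, DecayCurve | FLIMImage]:
    """The nine-step thinning ladder: fractions 0.1, 0.2, ..., 0.9."""
    fractions = np.round(np.arange(1, 10) * 0.1, 10)
    rng = np.random.default_rng(seed)
    return {
        float(f): thin_photons(data, float(f), seed=int(rng.integers(2**31)))
        for f in fractions
    }
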