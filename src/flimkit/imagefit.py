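"""Dataset-level operations: binning, thresholding, per-pixel fitting, maps.

``fit_image`` is the image-level entry point: it optionally bins the stack
spatially, masks dim pixels by total in-range photons, dispatches each
remaining pixel to the chosen fitter (RLD, LMA, global, phasor or Bayes) in
chunks, and assembles one 2-D map per fitted parameter plus reduced
chi-squared, mean-lifetime, intensity and validity-mask maps.  Results are
independent of the chunking/worker count because each pixel's fit is
deterministic and independent (global analysis is inherently whole-image and
single-pass).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .bayes import BayesGrid
from .core import (
    DataError,
    DecayCurve,
    FitError,
    FitRange,
    FLIMImage,
    full_range,
)
from .globalfit import fit_global
from .lma import FitConfig, fit_lma
from .phasor import phasor_image
from .rld import fit_rld

METHODS = ("rld", "lma", "global", "phasor", "bayes")


@dataclass
class ParamMaps:
    """Per-pixel parameter maps from an image-level fit.

    Pixels excluded by the intensity threshold (or whose fit failed) are 0 in
    ``mask`` and NaN in every parameter map; ``intensity`` always holds the
    in-range photon totals.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    intensity: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def param_names(self) -> list[str]:
        return list(self.maps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class FretEstimate:
    """FRET efficiency from donor / donor+acceptor lifetimes.

    efficiency = 1 - tau_donor_acceptor / tau_donor — the fractional lifetime
    reduction of the donor when energy transfer to an acceptor opens an extra
    de-excitation channel.
    """

    tau_donor: float | np.ndarray
    tau_donor_acceptor: float | np.ndarray
    efficiency: float | np.ndarray


def fret_efficiency(tau_donor, tau_donor_acceptor) -> FretEstimate:
    """FRET efficiency 1 - T_DA / T_D for scalars or maps."""
    td = np.asarray(tau_donor, dtype=float)
    tda = np.asarray(tau_donor_acceptor, dtype=float)
    if np.any(td[np.isfinite(td)] <= 0):
        raise DataError("donor lifetime must be positive")
    eff = 1.0 - tda / td
    if np.ndim(tau_donor) == 0 and np.ndim(tau_donor_acceptor) == 0:
        return FretEstimate(float(td), float(tda), float(eff))
    return FretEstimate(td, tda, eff)


def bin_image(image: FLIMImage, kernel_size: int, method: str = "fft") -> FLIMImage:
    """Spatial binning: per time bin, SUM counts over a k x k neighborhood.

    Summing (not averaging) preserves the Poisson photon statistics that the
    noise models assume.  Edges are zero-padded.  The default path convolves
    with the kernel by FFT; ``method='direct'`` uses spatial-domain
    convolution and must agree to ~1e-6 relative.
    """
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise DataError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if kernel_size == 1:
        return FLIMImage(image.grid, image.counts.copy())
    kernel = np.ones((1, kernel_size, kernel_size))
    if method == "fft":
        out = signal.fftconvolve(image.counts, kernel, mode="same")
        out = np.maximum(out, 0.0)  # FFT round-off can dip epsilon-negative
    elif method == "direct":
        out = ndimage.convolve(image.counts, kernel, mode="constant", cval=0.0)
    else:
        raise DataError(f"unknown binning method {method!r}")
    return FLIMImage(image.grid, out)


def crop_roi(
    image: FLIMImage,
    y0: int,
    y1: int,
    x0: int,
    x1: int,
    mask: Optional[np.ndarray] = None,
) -> FLIMImage:
    """Rectangular ROI crop ([y0, y1) x [x0, x1)); an optional boolean mask
    of the cropped shape zeroes excluded pixels."""
    H, W = image.shape
    if not (0 <= y0 < y1 <= H and 0 <= x0 < x1 <= W):
        raise DataError(f"ROI [{y0}:{y1}, {x0}:{x1}) outside image {H}x{W}")
    counts = image.counts[:, y0:y1, x0:x1].copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != counts.shape[1:]:
            raise DataError("ROI mask shape must match the cropped image")
        counts[:, ~mask] = 0.0
    return FLIMImage(image.grid, counts)


def _fit_chunk(method, Y, grid, config, n_components, model_kind, irf):
    """Fit a chunk of transients; returns a list of per-pixel param dicts."""
    out = []
    for row in Y:
        curve = DecayCurve(grid, row)
        try:
            if method == "rld":
                res = fit_rld(curve, config.fit_range, config.noise)
            else:
                res = fit_lma(
                    curve, config, irf=irf, n_components=n_components, kind=model_kind
                )
            d = dict(zip(res.spec.param_names(), res.spec.to_vector()))
            d["chisq_reduced"] = res.reduced_chisq
            out.append(d)
        except FitError:
            out.append(None)
    return out


def fit_image(
    image: FLIMImage,
    method: str = "lma",
    config: Optional[FitConfig] = None,
    intensity_threshold: float = 0.0,
    kernel_size: int = 1,
    n_components: int = 1,
    model_kind: str = "multi_exp",
    irf=None,
    tau_bounds: Optional[tuple[float, float]] = None,
    bayes_grid_size: tuple[int, int] = (200, 200),
    omega: Optional[float] = None,
    n_workers: int = 1,
    chunk_size: int = 512,
) -> ParamMaps:
    """Per-pixel fitting of a FLIM stack.

    Bins spatially (``kernel_size``), masks pixels whose total in-range
    photons fall below ``intensity_threshold`` (NaN in all parameter maps),
    and fits the remaining pixels with the chosen method.  Deterministic
    given the configuration, and invariant to ``chunk_size``/``n_workers``.
    """
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; choose from {METHODS}")
    if config is None:
        config = FitConfig()
    if kernel_size != 1:
        image = bin_image(image, kernel_size)
    grid = image.grid
    fr = config.fit_range or full_range(grid)
    fr.validate(grid)

    intensity = image.intensity(fr)
    mask = intensity >= intensity_threshold
    if not mask.any():
        raise FitError("no pixel above the intensity threshold")
    H, W = image.shape
    meta = {
        "method": method,
        "kernel_size": kernel_size,
        "intensity_threshold": intensity_threshold,
        "fit_range": [fr.start_bin, fr.end_bin],
        "noise": config.noise.kind,
        "n_components": n_components,
    }

    if method == "global":
        gres = fit_global(
            image,
            n_components=n_components,
            config=config,
            intensity_threshold=intensity_threshold,
        )
        maps = dict(gres.maps)
        _attach_mean_lifetime(maps, n_components)
        fitted_mask = gres.mask & np.isfinite(maps.get("Z", np.nan * intensity))
        meta["global_tau"] = [float(v) for v in gres.global_tau]
        return ParamMaps(maps, fitted_mask, intensity, method, meta)

    if method == "phasor":
        ph = phasor_image(image, fr, omega=omega)
        om = ph.pop("omega")
        maps = {k: np.where(mask, v, np.nan) for k, v in ph.items()}
        meta["omega_rad_per_ns"] = float(om)
        meta["frequency_mhz"] = float(om / (2 * np.pi) * 1e3)
        valid = mask & np.isfinite(maps["g"])
        return ParamMaps(maps, valid, intensity, method, meta)

    n = len(fr)
    Y = image.counts[fr.slice].reshape(n, -1).T          # (P, n)
    flat_mask = mask.ravel()
    Ysel = Y[flat_mask]

    if method == "bayes":
        bg = BayesGrid(grid, fr, tau_bounds=tau_bounds, grid_size=bayes_grid_size)
        res = bg.fit_many(Ysel)
        maps = {}
        for key, name in (("tau", "tau1"), ("tau_std", "tau_std"), ("b", "b"),):
            full = np.full(H * W, np.nan)
            full[flat_mask] = res[key]
            maps[name] = full.reshape(H, W)
        valid = mask & np.isfinite(maps["tau1"])
        meta["tau_bounds"] = list(bg.tau_grid[[0, -1]].astype(float))
        return ParamMaps(maps, valid, intensity, method, meta)

    # rld / lma: chunked per-pixel fitting
    chunks = [Ysel[s : s + chunk_size] for s in range(0, Ysel.shape[0], chunk_size)]
    args = (method, grid, config, n_components, model_kind, irf)
    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(
                pool.map(lambda c: _fit_chunk(args[0], c, *args[1:]), chunks)
            )
    else:
        results = [_fit_chunk(args[0], c, *args[1:]) for c in chunks]
    per_pixel = [d for chunk in results for d in chunk]

    names = None
    for d in per_pixel:
        if d is not None:
            names = list(d)
            break
    if names is None:
        raise FitError("every per-pixel fit failed")
    maps = {nm: np.full(H * W, np.nan) for nm in names}
    ok = np.zeros(H * W, dtype=bool)
    sel_idx = np.flatnonzero(flat_mask)
    for idx, d in zip(sel_idx, per_pixel):
        if d is None:
            continue
        ok[idx] = True
        for nm in names:
            maps[nm][idx] = d[nm]
    maps = {nm: v.reshape(H, W) for nm, v in maps.items()}
    _attach_mean_lifetime(maps, n_components)
    return ParamMaps(maps, ok.reshape(H, W), intensity, method, meta)


def _tau_amp_pairs(maps: dict[str, np.ndarray]):
    pairs = []
    i = 1
    while f"tau{i}" in maps:
        amp = maps.get(f"A{i}", maps.get("A") if i == 1 else None)
        if amp is None:
            amp = np.ones_like(maps[f"tau{i}"])
        pairs.append((amp, maps[f"tau{i}"]))
        i += 1
    if not pairs and "tau" in maps:
        amp = maps.get("A", np.ones_like(maps["tau"]))
        pairs.append((amp, maps["tau"]))
    return pairs


def _attach_mean_lifetime(maps: dict[str, np.ndarray], n_components: int) -> None:
    pairs = _tau_amp_pairs(maps)
    if pairs:
        maps["tau_mean"] = _weighted_mean_tau(pairs, "amplitude")


def _weighted_mean_tau(pairs, weighting: str) -> np.ndarray:
    A = np.stack([a for a, _ in pairs])
    T = np.stack([t for _, t in pairs])
    with np.errstate(invalid="ignore", divide="ignore"):
        if weighting == "amplitude":
            num, den = (A * T).sum(axis=0), A.sum(axis=0)
        elif weighting == "intensity":
            num, den = (A * T * T).sum(axis=0), (A * T).sum(axis=0)
        else:
            raise DataError(f"unknown weighting {weighting!r}")
        out = num / den
    return np.where(den > 0, out, np.nan)


def mean_lifetime_map(maps: ParamMaps | dict, weighting: str = "amplitude") -> np.ndarray:
    """Mean lifetime per pixel.

    ``amplitude`` weighting: sum A_i tau_i / sum A_i (fraction of excited
    molecules); ``intensity`` weighting: sum A_i tau_i^2 / sum A_i tau_i
    (fraction of detected photons).  A single-component fit returns its tau
    map unchanged; pixels with non-positive total amplitude are NaN.
    """
    d = maps.maps if isinstance(maps, ParamMaps) else maps
    pairs = _tau_amp_pairs(d)
    if not pairs:
        raise DataError("no lifetime maps present")
    if len(pairs) == 1:
        amp, tau = pairs[0]
        return np.where(amp > 0, tau, np.nan)
    return _weighted_mean_tau(pairs, weighting)
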