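"""Single-molecule detection and maximum-likelihood localization.

Each candidate emitter is fitted in a small square ROI with the
pixel-integrated Gaussian PSF model ``mu_k = N * Ex_k * Ey_k + b`` under a
Poisson pixel likelihood.  Parameters (x, y, N, b) — optionally also the PSF
width — are refined by sequential per-parameter Newton-Raphson updates.
Localization precision is the Cramér-Rao lower bound from the Fisher
information of the pixel model, and goodness of fit is the Poisson deviance
(likelihood ratio against the saturated model) referred to a chi-square law
with ``roi_size**2 - n_params`` degrees of freedom.

Accepted localizations satisfy the acquisition filters: background at most
``max_background`` photons, at least ``min_photons`` photons per frame per
emitter, and a goodness-of-fit p-value of at least ``p_cutoff``
(defaults 200 / 250 / 0.01; thresholds are inclusive for acceptance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import chi2

from .psf import (
    integrated_gaussian_derivs,
    integrated_gaussian_dsigma,
)
from .simulate import MovieStack, adu_to_photons

__all__ = [
    "FitConfig",
    "Localization",
    "detect_candidates",
    "fit_mle",
    "filter_localizations",
    "localize_stack",
]

#: Column set of a localization table.
LOC_COLUMNS = [
    "frame", "x", "y", "photons", "background",
    "crlb_x", "crlb_y", "loglike", "pvalue", "accepted", "reason",
]


@dataclass(frozen=True)
class FitConfig:
    """Detection, fitting, and filtering parameters.

    ``psf_sigma`` is held fixed during the 4-parameter fit (set
    ``fit_sigma=True`` for a 5-parameter fit that refines it).
    ``detection_threshold`` is in photons, applied to the band-pass
    (difference-of-Gaussians) filtered image.
    """

    roi_size: int = 7
    psf_sigma: float = 1.3
    max_iterations: int = 20
    detection_threshold: float = 5.0
    max_background: float = 200.0
    min_photons: float = 250.0
    p_cutoff: float = 0.01
    fit_sigma: bool = False

    def __post_init__(self) -> None:
        if self.roi_size < 5 or self.roi_size % 2 == 0:
            raise ValueError("roi_size must be odd and >= 5")
        for name in ("detection_threshold", "max_background", "min_photons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ValueError("p_cutoff must be in [0, 1]")

    @property
    def n_params(self) -> int:
        return 5 if self.fit_sigma else 4


@dataclass(frozen=True)
class Localization:
    """One fitted emitter appearance in one frame.

    Positions are sub-pixel, 0-based: ``x = 3.0`` is the center of pixel
    column 3.  ``crlb_x``/``crlb_y`` are standard-deviation lower bounds in
    pixels.
    """

    frame: int
    x: float
    y: float
    photons: float
    background: float
    crlb_x: float
    crlb_y: float
    loglike: float
    pvalue: float
    accepted: bool = True
    reason: str = ""
    psf_sigma: float = np.nan


def detect_candidates(image: np.ndarray, config: FitConfig) -> list[tuple[int, int]]:
    """Find candidate emitter pixels in a single photon-unit frame.

    Band-pass filters the frame (difference of Gaussians at ``psf_sigma`` and
    ``2 * psf_sigma``), then takes local maxima above
    ``detection_threshold``.  Maxima closer than ``roi_size / 2`` are merged
    keeping the brighter (ties: smaller row, then smaller column), and
    candidates whose ROI would clip the frame border are discarded.

    Returns ``(row, col)`` pixel indices.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    dog = (
        ndimage.gaussian_filter(image, config.psf_sigma)
        - ndimage.gaussian_filter(image, 2.0 * config.psf_sigma)
    )
    return _maxima_from_dog(dog, config)


def _maxima_from_dog(dog: np.ndarray, config: FitConfig) -> list[tuple[int, int]]:
    rows, cols = dog.shape
    local_max = (dog == ndimage.maximum_filter(dog, size=3)) & (
        dog > config.detection_threshold
    )
    rr, cc = np.nonzero(local_max)
    if len(rr) == 0:
        return []
    # brightness-desc order; ties by smaller row then col
    order = np.lexsort((cc, rr, -dog[rr, cc]))
    rr, cc = rr[order], cc[order]
    merge_r = config.roi_size / 2.0
    kept: list[tuple[int, int]] = []
    for r, c in zip(rr, cc):
        if all((r - rk) ** 2 + (c - ck) ** 2 >= merge_r**2 for rk, ck in kept):
            kept.append((int(r), int(c)))
    half = config.roi_size // 2
    return [
        (r, c)
        for r, c in kept
        if half <= r < rows - half and half <= c < cols - half
    ]


def _fit_rois(rois: np.ndarray, config: FitConfig) -> dict[str, np.ndarray]:
    """Vectorized per-parameter Newton-Raphson MLE over a batch of ROIs.

    ``rois`` is (n, K, K) in photon units.  Returns parameter arrays, CRLBs,
    log-likelihood, deviance p-value, and a per-ROI failure reason
    ("" = fit usable).
    """
    d = np.asarray(rois, dtype=float)
    n, K, K2 = d.shape[0], d.shape[1], d.shape[1] ** 2
    k_idx = np.arange(K, dtype=float)

    # Initialization: background from the ROI minimum, photons from the
    # background-subtracted sum, position from the center of mass.
    b = d.reshape(n, -1).min(axis=1)
    N = np.maximum(d.reshape(n, -1).sum(axis=1) - K2 * b, 10.0)
    w = np.maximum(d - b[:, None, None], 0.0)
    wsum = np.maximum(w.sum(axis=(1, 2)), 1e-12)
    x = (w.sum(axis=1) * k_idx).sum(axis=1) / wsum
    y = (w.sum(axis=2) * k_idx).sum(axis=1) / wsum
    b = np.maximum(b, 0.01)
    sigma = np.full(n, float(config.psf_sigma))

    param_names = ["x", "y", "N", "b"] + (["sigma"] if config.fit_sigma else [])
    max_step = {"x": 1.0, "y": 1.0, "N": None, "b": 5.0, "sigma": 0.2}

    def axis_terms(center, sig):
        return integrated_gaussian_derivs(k_idx[None, :], center[:, None], sig[:, None])

    for _ in range(config.max_iterations):
        for name in param_names:
            Ex, dEx, d2Ex = axis_terms(x, sigma)
            Ey, dEy, d2Ey = axis_terms(y, sigma)
            mu = N[:, None, None] * Ey[:, :, None] * Ex[:, None, :] + b[:, None, None]
            mu = np.maximum(mu, 1e-9)
            if name == "x":
                dmu = N[:, None, None] * Ey[:, :, None] * dEx[:, None, :]
                d2mu = N[:, None, None] * Ey[:, :, None] * d2Ex[:, None, :]
            elif name == "y":
                dmu = N[:, None, None] * dEy[:, :, None] * Ex[:, None, :]
                d2mu = N[:, None, None] * d2Ey[:, :, None] * Ex[:, None, :]
            elif name == "N":
                dmu = Ey[:, :, None] * Ex[:, None, :]
                d2mu = np.zeros_like(dmu)
            elif name == "b":
                dmu = np.ones_like(mu)
                d2mu = np.zeros_like(mu)
            else:  # sigma
                dsx, d2sx = integrated_gaussian_dsigma(
                    k_idx[None, :], x[:, None], sigma[:, None])
                dsy, d2sy = integrated_gaussian_dsigma(
                    k_idx[None, :], y[:, None], sigma[:, None])
                dmu = N[:, None, None] * (
                    dsy[:, :, None] * Ex[:, None, :]
                    + Ey[:, :, None] * dsx[:, None, :]
                )
                d2mu = N[:, None, None] * (
                    d2sy[:, :, None] * Ex[:, None, :]
                    + 2.0 * dsy[:, :, None] * dsx[:, None, :]
                    + Ey[:, :, None] * d2sx[:, None, :]
                )
            ratio = d / mu - 1.0
            grad = (ratio * dmu).sum(axis=(1, 2))
            hess = (ratio * d2mu - d * dmu**2 / mu**2).sum(axis=(1, 2))
            hess = np.where(hess < -1e-12, hess, -1e-12)
            step = -grad / hess  # Newton: theta <- theta - g/h
            cap = max_step[name]
            if name == "N":
                cap_arr = np.maximum(100.0, 0.5 * N)
                step = np.clip(step, -cap_arr, cap_arr)
            elif cap is not None:
                step = np.clip(step, -cap, cap)
            if name == "x":
                x = x + step
            elif name == "y":
                y = y + step
            elif name == "N":
                N = np.maximum(N + step, 1e-3)
            elif name == "b":
                b = np.maximum(b + step, 1e-6)
            else:
                sigma = np.clip(sigma + step, 0.3, K / 2.0)

    # Final model, likelihood, deviance, Fisher information.
    Ex, dEx, _ = axis_terms(x, sigma)
    Ey, dEy, _ = axis_terms(y, sigma)
    mu = N[:, None, None] * Ey[:, :, None] * Ex[:, None, :] + b[:, None, None]
    mu = np.maximum(mu, 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        dlnd = d * np.log(d / mu)
        dlnd[d == 0] = 0.0
    deviance = 2.0 * (mu - d + dlnd).sum(axis=(1, 2))
    dof = K2 - config.n_params
    pvalue = chi2.sf(deviance, dof)
    from scipy.special import gammaln
    loglike = (d * np.log(mu) - mu - gammaln(d + 1.0)).sum(axis=(1, 2))

    jac = [
        (N[:, None, None] * Ey[:, :, None] * dEx[:, None, :]),
        (N[:, None, None] * dEy[:, :, None] * Ex[:, None, :]),
        (Ey[:, :, None] * Ex[:, None, :]),
        np.ones_like(mu),
    ]
    if config.fit_sigma:
        dsx, _ = integrated_gaussian_dsigma(k_idx[None, :], x[:, None], sigma[:, None])
        dsy, _ = integrated_gaussian_dsigma(k_idx[None, :], y[:, None], sigma[:, None])
        jac.append(N[:, None, None] * (
            dsy[:, :, None] * Ex[:, None, :] + Ey[:, :, None] * dsx[:, None, :]
        ))
    J = np.stack([j.reshape(n, -1) for j in jac], axis=1)  # (n, P, K^2)
    fisher = np.einsum("npk,nqk->npq", J / mu.reshape(n, 1, -1), J)

    P = config.n_params
    crlb = np.full((n, P), np.nan)
    reason = np.array([""] * n, dtype=object)
    with np.errstate(all="ignore"):
        dets = np.linalg.det(fisher)
        ok = np.isfinite(dets) & (dets > 0)
        if ok.any():
            inv = np.linalg.inv(fisher[ok])
            var = np.einsum("npp->np", inv)
            bad_var = (var <= 0).any(axis=1) | ~np.isfinite(var).all(axis=1)
            crlb_ok = np.sqrt(np.maximum(var, 0))
            crlb[ok] = crlb_ok
            idx_ok = np.flatnonzero(ok)
            reason[idx_ok[bad_var]] = "singular_fisher"
    reason[~ok] = "singular_fisher"

    # Divergence: fitted center left the ROI.
    out = (x < -0.5) | (x > K - 0.5) | (y < -0.5) | (y > K - 0.5)
    reason[out & (reason == "")] = "diverged"

    return {
        "x": x, "y": y, "photons": N, "background": b, "psf_sigma": sigma,
        "crlb_x": crlb[:, 0], "crlb_y": crlb[:, 1],
        "loglike": loglike, "pvalue": pvalue, "deviance": deviance,
        "fit_reason": reason,
    }


def fit_mle(roi: np.ndarray, config: FitConfig | None = None) -> Localization:
    """Fit a single ROI (``roi_size`` square, photon units); see module docs."""
    config = config or FitConfig()
    roi = np.asarray(roi, dtype=float)
    if roi.shape != (config.roi_size, config.roi_size):
        raise ValueError(
            f"roi must be {config.roi_size} x {config.roi_size}, got {roi.shape}"
        )
    r = _fit_rois(roi[None], config)
    failed = bool(r["fit_reason"][0])
    return Localization(
        frame=0, x=float(r["x"][0]), y=float(r["y"][0]),
        photons=float(r["photons"][0]), background=float(r["background"][0]),
        crlb_x=float(r["crlb_x"][0]), crlb_y=float(r["crlb_y"][0]),
        loglike=float(r["loglike"][0]), pvalue=float(r["pvalue"][0]),
        accepted=not failed, reason=str(r["fit_reason"][0]),
        psf_sigma=float(r["psf_sigma"][0]),
    )


def filter_localizations(locs: pd.DataFrame, config: FitConfig | None = None) -> pd.DataFrame:
    """Apply the acceptance thresholds, preserving order and fitted values.

    A localization is accepted iff ``background <= max_background`` AND
    ``photons >= min_photons`` AND ``pvalue >= p_cutoff`` (inclusive) and its
    fit did not fail.  Rejection reasons are recorded per row
    (comma-separated when several thresholds fail).
    """
    config = config or FitConfig()
    out = locs.copy()
    reasons = []
    for _, row in out.iterrows():
        why = []
        prior = str(row.get("reason", "") or "")
        if prior:
            why.append(prior)
        if row["background"] > config.max_background:
            why.append("max_background")
        if row["photons"] < config.min_photons:
            why.append("min_photons")
        if not (row["pvalue"] >= config.p_cutoff):
            why.append("pvalue")
        reasons.append(",".join(why))
    out["reason"] = reasons
    out["accepted"] = [r == "" for r in reasons]
    return out


def _filter_fast(out: pd.DataFrame, config: FitConfig) -> pd.DataFrame:
    """Vectorized equivalent of :func:`filter_localizations` for large tables."""
    prior = out["reason"].fillna("").astype(str).to_numpy()
    bg = out["background"].to_numpy() > config.max_background
    ph = out["photons"].to_numpy() < config.min_photons
    pv = ~(out["pvalue"].to_numpy() >= config.p_cutoff)
    reasons = [
        ",".join(
            ([p] if p else [])
            + (["max_background"] if f1 else [])
            + (["min_photons"] if f2 else [])
            + (["pvalue"] if f3 else [])
        )
        for p, f1, f2, f3 in zip(prior, bg, ph, pv)
    ]
    out = out.copy()
    out["reason"] = reasons
    out["accepted"] = [r == "" for r in reasons]
    return out


def localize_stack(movie: MovieStack, config: FitConfig | None = None) -> pd.DataFrame:
    """Detect, fit, and filter every frame of a movie.

    Returns one row per fitted candidate with the standard column set
    (positions in full-frame pixel coordinates) plus the detection ROI
    corner.  Deterministic: the same movie yields the identical table.
    """
    config = config or FitConfig()
    if movie.units == "adu":
        movie = adu_to_photons(movie)
    frames = np.asarray(movie.frames, dtype=float)
    if not np.all(np.isfinite(frames)):
        raise ValueError("movie contains non-finite pixels")
    half = config.roi_size // 2

    # Band-pass the whole stack at once, then per-frame maxima.
    dog = (
        ndimage.gaussian_filter(frames, (0, config.psf_sigma, config.psf_sigma))
        - ndimage.gaussian_filter(frames, (0, 2 * config.psf_sigma, 2 * config.psf_sigma))
    )
    rois, meta = [], []
    for f in range(frames.shape[0]):
        for r, c in _maxima_from_dog(dog[f], config):
            rois.append(frames[f, r - half : r + half + 1, c - half : c + half + 1])
            meta.append((f, r - half, c - half))
    if not rois:
        return pd.DataFrame(columns=LOC_COLUMNS + ["roi_row", "roi_col", "psf_sigma"])

    fit = _fit_rois(np.stack(rois), config)
    meta = np.asarray(meta)
    table = pd.DataFrame({
        "frame": meta[:, 0],
        "x": fit["x"] + meta[:, 2],
        "y": fit["y"] + meta[:, 1],
        "photons": fit["photons"],
        "background": fit["background"],
        "crlb_x": fit["crlb_x"],
        "crlb_y": fit["crlb_y"],
        "loglike": fit["loglike"],
        "pvalue": fit["pvalue"],
        "reason": fit["fit_reason"],
        "roi_row": meta[:, 1],
        "roi_col": meta[:, 2],
        "psf_sigma": fit["psf_sigma"],
    })
    return _filter_fast(table, config)
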