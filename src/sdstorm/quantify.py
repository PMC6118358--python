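"""Quantitative outputs: super-resolution renders, time-course traces,
cross-talk ratios, per-round counts, and inter-round registration.

Cross-talk follows the published definition: the ratio of accepted
localization counts after invader treatment to the count before, measured on
equal-length acquisitions under identical filters (counts scale with frame
number, so matched lengths are required, not assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import MovieStack

__all__ = [
    "SRImage",
    "CrosstalkResult",
    "RoundCounts",
    "render",
    "movie_to_trace",
    "crosstalk",
    "round_counts",
    "register_rounds",
]


class RegistrationError(RuntimeError):
    """Cross-correlation registration failed (e.g. zero-variance image)."""


@dataclass
class SRImage:
    """A rendered super-resolution image.

    Each accepted localization contributes a unit-integral 2-D Gaussian with
    per-axis widths equal to its localization precisions (CRLB), so the total
    image mass equals the number of rendered localizations.
    """

    pixels: np.ndarray
    zoom: float
    extent: tuple[float, float, float, float]  # x0, x1, y0, y1 in camera px
    n_rendered: int
    n_flagged_wide: int = 0  # localizations with crlb > 1 camera pixel

    @property
    def mass(self) -> float:
        return float(self.pixels.sum())


def render(
    locs: pd.DataFrame,
    zoom: float = 10.0,
    extent: tuple[float, float, float, float] | None = None,
    *,
    truncate_sigmas: float = 5.0,
    accepted_only: bool = True,
) -> SRImage:
    """Render localizations as a sum of unit-mass CRLB-width Gaussians.

    Each emitter's stamp is truncated at ``truncate_sigmas`` and discretely
    normalized to exactly unit mass.  Localizations with a precision worse
    than one camera pixel are rendered but counted in ``n_flagged_wide``;
    nothing is silently dropped.  An empty input yields a zero image with a
    warning.
    """
    if accepted_only and "accepted" in locs.columns:
        locs = locs[locs["accepted"]]
    if extent is None:
        if len(locs) == 0:
            extent = (0.0, 1.0, 0.0, 1.0)
        else:
            extent = (
                float(np.floor(locs["x"].min() - 1)),
                float(np.ceil(locs["x"].max() + 1)),
                float(np.floor(locs["y"].min() - 1)),
                float(np.ceil(locs["y"].max() + 1)),
            )
    x0, x1, y0, y1 = extent
    W = int(np.ceil((x1 - x0) * zoom))
    H = int(np.ceil((y1 - y0) * zoom))
    img = np.zeros((H, W))
    if len(locs) == 0:
        warnings.warn("render: no localizations to draw; returning zero image")
        return SRImage(pixels=img, zoom=zoom, extent=extent, n_rendered=0)

    finite = np.isfinite(locs["crlb_x"].to_numpy()) & np.isfinite(locs["crlb_y"].to_numpy())
    if not finite.all():
        raise ValueError("render requires finite crlb values")

    n_wide = int(((locs["crlb_x"] > 1) | (locs["crlb_y"] > 1)).sum())
    n_drawn = 0
    for x, y, sx, sy in locs[["x", "y", "crlb_x", "crlb_y"]].itertuples(index=False):
        cx = (x - x0) * zoom
        cy = (y - y0) * zoom
        sxz, syz = max(sx * zoom, 0.5), max(sy * zoom, 0.5)
        rx = int(np.ceil(truncate_sigmas * sxz))
        ry = int(np.ceil(truncate_sigmas * syz))
        c0, c1 = int(np.floor(cx)) - rx, int(np.floor(cx)) + rx + 1
        r0, r1 = int(np.floor(cy)) - ry, int(np.floor(cy)) + ry + 1
        c0, c1 = max(c0, 0), min(c1, W)
        r0, r1 = max(r0, 0), min(r1, H)
        if c0 >= c1 or r0 >= r1:
            continue
        gx = np.exp(-0.5 * ((np.arange(c0, c1) - cx) / sxz) ** 2)
        gy = np.exp(-0.5 * ((np.arange(r0, r1) - cy) / syz) ** 2)
        stamp = np.outer(gy, gx)
        img[r0:r1, c0:c1] += stamp / stamp.sum()
        n_drawn += 1
    return SRImage(pixels=img, zoom=zoom, extent=extent,
                   n_rendered=n_drawn, n_flagged_wide=n_wide)


def movie_to_trace(
    movie: MovieStack,
    background_percentile: float = 20.0,
    *,
    smooth_sigma_px: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduce a time-course movie to a normalized intensity trace.

    Per frame, a scalar background offset is estimated as the given
    percentile of a Gaussian-smoothed copy of the frame (smoothing suppresses
    the shot-noise bias a percentile of raw Poisson pixels would carry); the
    offset is subtracted from the frame sum, which is clamped at zero.  The
    trace is then normalized to its maximum.  Returns ``(times_s, summed,
    normalized)``.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames for a trace")
    frames = np.asarray(movie.frames, dtype=float)
    n_pix = frames.shape[1] * frames.shape[2]
    smooth = ndimage.gaussian_filter(frames, (0, smooth_sigma_px, smooth_sigma_px))
    offsets = np.percentile(smooth.reshape(movie.n_frames, -1),
                            background_percentile, axis=1)
    summed = np.maximum(frames.sum(axis=(1, 2)) - offsets * n_pix, 0.0)
    peak = summed.max()
    if peak <= 0:
        # offset subtraction removed everything (e.g. a constant movie):
        # fall back to the raw sums so a flat movie yields a flat unit trace
        summed = frames.sum(axis=(1, 2))
        peak = summed.max()
        if peak <= 0:
            raise ValueError("trace is identically zero")
        warnings.warn("background offset removed all signal; trace computed "
                      "from raw frame sums")
    return movie.times_s(), summed, summed / peak


@dataclass(frozen=True)
class CrosstalkResult:
    """After/before accepted-localization ratio: the cross-talk measure."""

    n_before: int
    n_after: int

    @property
    def ratio(self) -> float:
        return self.n_after / self.n_before

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def _count(locs) -> int:
    if isinstance(locs, pd.DataFrame):
        if "accepted" in locs.columns:
            return int(locs["accepted"].sum())
        return len(locs)
    return int(locs)


def crosstalk(locs_before, locs_after) -> CrosstalkResult:
    """Cross-talk: accepted localizations after invader over those before.

    Both tables must come from equal-length acquisitions filtered with the
    same configuration.  Accepts localization tables or raw counts.
    """
    n_before, n_after = _count(locs_before), _count(locs_after)
    if n_before <= 0:
        raise ZeroDivisionError("crosstalk undefined: no localizations before invader")
    return CrosstalkResult(n_before=n_before, n_after=n_after)


@dataclass
class RoundCounts:
    """Accepted localization counts per (round, target) with per-target
    dispersion across rounds (coefficient of variation; NaN = not applicable
    for a single round)."""

    table: pd.DataFrame  # columns: round, target_id, count
    cv_per_target: dict[str, float]


def round_counts(locs: pd.DataFrame) -> RoundCounts:
    """Tabulate accepted counts per (round, target) and their stability.

    ``locs`` needs columns ``round``, ``target_id`` and (optionally)
    ``accepted``.  The CV across rounds is the relabeling-robustness measure:
    comparable counts over repeated rounds mean the label-image-remove cycle
    neither loses nor gains signal.
    """
    df = locs
    if "accepted" in df.columns:
        df = df[df["accepted"]]
    grouped = (
        df.groupby(["round", "target_id"], sort=True).size().reset_index(name="count")
    )
    cv: dict[str, float] = {}
    for target, sub in grouped.groupby("target_id"):
        counts = sub["count"].to_numpy(dtype=float)
        cv[str(target)] = (
            float(counts.std(ddof=1) / counts.mean()) if len(counts) > 1 else float("nan")
        )
    return RoundCounts(table=grouped, cv_per_target=cv)


def register_rounds(image_a: np.ndarray, image_b: np.ndarray) -> tuple[float, float]:
    """Estimate the (dx, dy) shift of image B relative to image A.

    Normalized cross-correlation via FFT over all integer shifts, refined to
    sub-pixel precision by parabolic interpolation of the correlation peak.
    ``B(x, y) ~ A(x - dx, y - dy)``: applying ``(-dx, -dy)`` to B's
    localizations aligns them onto A.  A computational stand-in for
    brightfield-reference re-alignment between rounds.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        raise RegistrationError("flat image: registration impossible")
    # Zero-padded circular cross-correlation corr(s) = sum_x a(x) b(x + s)
    H, W = a.shape
    fa = np.fft.rfft2(a, s=(2 * H, 2 * W))
    fb = np.fft.rfft2(b, s=(2 * H, 2 * W))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(2 * H, 2 * W))
    corr /= (np.sqrt((a**2).sum() * (b**2).sum()))
    peak = np.unravel_index(np.argmax(corr), corr.shape)

    def refine(axis: int) -> float:
        p = list(peak)
        c0 = corr[tuple(p)]
        p[axis] = (peak[axis] - 1) % corr.shape[axis]
        cm = corr[tuple(p)]
        p[axis] = (peak[axis] + 1) % corr.shape[axis]
        cp = corr[tuple(p)]
        denom = cm - 2 * c0 + cp
        return 0.0 if denom == 0 else 0.5 * (cm - cp) / denom

    dy = peak[0] + refine(0)
    dx = peak[1] + refine(1)
    if dy > H:
        dy -= 2 * H
    if dx > W:
        dx -= 2 * W
    return float(dx), float(dy)
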