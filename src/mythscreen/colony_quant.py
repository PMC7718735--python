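"""Per-spot colony density and area extraction from arrayed plate images.

The quantitative readout of an arrayed growth screen is one scalar per
pinned spot.  Two quantities are extracted:

* **density** (selective test plates): integrated above-background intensity
  over the spot window, with the local background estimated from the annulus
  between the spot and its neighbours.  Integrated intensity is monotone in
  both colony size and opacity — it tracks how growth strength is read by
  eye — and is linear in the synthetic generator's truth, which makes it the
  right readout to validate against ground truth.
* **area** (diploid-selection plates): foreground pixel count per spot
  window after a global automatic (Otsu) threshold.  Diploid colony area
  measures mating success and is used to normalize test densities.

Test densities are divided by the min–max-normalized diploid area of the
corresponding source well; spots whose diploid colony is essentially absent
(normalized area below ``epsilon``) are flagged ``failed_mating`` instead of
being divided by a vanishing number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "GridFit",
    "LowSignalError",
    "fit_grid",
    "measure_density",
    "measure_area",
    "minmax_normalize",
    "normalize_densities",
]


class LowSignalError(ValueError):
    """Raised when too few spots are detectable to fit a plate grid.

    Advises a manual origin/pitch override (see ``fit_grid``'s ``origin`` and
    ``pitch`` arguments).
    """


@dataclass
class GridFit:
    """Fitted spot-centre lattice for an arrayed plate image."""

    n_rows: int
    n_cols: int
    centers: np.ndarray  # (n_rows, n_cols, 2) of (y, x), 0-based pixels
    pitch: float
    fit_residual: float  # RMS refined-vs-lattice displacement, pixels

    def __post_init__(self) -> None:
        if self.centers.shape != (self.n_rows, self.n_cols, 2):
            raise ValueError("centers must have shape (n_rows, n_cols, 2)")


def _axis_lattice(profile: np.ndarray, n: int) -> tuple[float, float, int]:
    """Fit origin + pitch to one axis from an intensity-projection profile.

    Returns (origin, pitch, n_peaks_used).  Peaks are local maxima of the
    smoothed above-baseline profile; the lattice is fit by least squares
    after assigning each peak to its nearest integer index.
    """
    from scipy.signal import find_peaks

    smooth = ndi.gaussian_filter1d(profile.astype(float), 2.0)
    prof = np.clip(smooth - np.median(smooth), 0.0, None)
    if prof.max() <= 0:
        raise LowSignalError(
            "no detectable spots along an axis; pass origin/pitch manually"
        )
    peaks, _ = find_peaks(prof, height=0.2 * prof.max(), distance=3)
    if len(peaks) < max(2, int(np.ceil(0.1 * n))):
        raise LowSignalError(
            f"only {len(peaks)} spot peaks found for {n} expected positions; "
            "pass origin/pitch manually"
        )
    # Lattice template matching: scan candidate (pitch, origin) pairs and
    # score each by the profile's local contrast at the n lattice positions
    # — the value at each position minus the mean at the half-pitch valleys
    # beside it.  The correct lattice aligns *every* position (bright hits
    # and the faint residual growth of non-interactors alike), which makes
    # this robust to sparse, clumped plates where peak-gap or Fourier-phase
    # estimates are underdetermined, and the valley term cancels smooth
    # illumination gradients exactly to first order.
    L = len(smooth)
    lo = L / (n + 4.0)
    hi = (L - 1.0) / max(n - 1, 1)
    if hi < 3.0:
        raise LowSignalError("profile too short for the requested grid")
    k = np.arange(n, dtype=float)
    xs = np.arange(L, dtype=float)
    best_score, origin, pitch = -np.inf, 0.0, hi
    for p in np.linspace(max(lo, 3.0), hi, 400):
        max_o = (L - 1.0) - (n - 1) * p
        origins = np.arange(0.0, max_o + 1e-9, 0.25)
        pos = origins[:, None] + p * k[None, :]
        val = np.interp(pos, xs, smooth)
        valley = 0.5 * (
            np.interp(pos - p / 2.0, xs, smooth) + np.interp(pos + p / 2.0, xs, smooth)
        )
        scores = (val - valley).sum(axis=1)
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score, origin, pitch = float(scores[i]), float(origins[i]), float(p)
    return origin, pitch, len(peaks)


def fit_grid(
    image: np.ndarray,
    n_rows: int,
    n_cols: int,
    origin: Optional[tuple[float, float]] = None,
    pitch: Optional[float] = None,
) -> GridFit:
    """Estimate the spot-centre lattice of an n_rows × n_cols arrayed plate.

    Pitch and origin are estimated from peaks of the row/column intensity
    projections, then every centre is refined to the local intensity
    centroid within a half-pitch window.  ``origin``/``pitch`` can be given
    explicitly to override detection (the recovery path for low-signal
    plates).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if origin is None or pitch is None:
        oy, py, _ = _axis_lattice(img.sum(axis=1), n_rows)
        ox, px, _ = _axis_lattice(img.sum(axis=0), n_cols)
    else:
        oy, ox = origin
        py = px = float(pitch)
    lattice = np.zeros((n_rows, n_cols, 2))
    lattice[..., 0] = oy + py * np.arange(n_rows)[:, None]
    lattice[..., 1] = ox + px * np.arange(n_cols)[None, :]

    mean_pitch = 0.5 * (py + px)
    half = mean_pitch / 2.0
    centers = lattice.copy()
    shifts = []
    n_signal = 0
    for r in range(n_rows):
        for c in range(n_cols):
            cy, cx = lattice[r, c]
            y0, y1 = int(max(0, round(cy - half))), int(min(img.shape[0], round(cy + half) + 1))
            x0, x1 = int(max(0, round(cx - half))), int(min(img.shape[1], round(cx + half) + 1))
            win = img[y0:y1, x0:x1]
            if win.size == 0:
                continue
            med = np.median(win)
            # noise from the below-median (background) half so bright colony
            # pixels cannot inflate the estimate
            lower = med - win[win <= med]
            noise = 1.4826 * float(np.median(lower)) if lower.size else 0.0
            amp = win.max() - med
            # refine only where there is real signal above the local floor;
            # the centroid uses only above-half-maximum pixels (the colony
            # plateau), which is insensitive to the noise floor and to
            # neighbouring colonies' shoulders leaking into the window
            if amp > 5.0 * noise and amp > 0:
                sig = np.clip(win - med, 0.0, None)
                sig[sig < 0.5 * amp] = 0.0
                tot = sig.sum()
                yy, xx = np.mgrid[y0:y1, x0:x1]
                ry = (yy * sig).sum() / tot
                rx = (xx * sig).sum() / tot
                dy, dx = ry - cy, rx - cx
                if np.hypot(dy, dx) <= half:
                    centers[r, c] = (ry, rx)
                    shifts.append((dy, dx))
                    n_signal += 1
    residual = float(np.sqrt(np.mean(np.square(shifts)))) if shifts else 0.0
    return GridFit(n_rows, n_cols, centers, mean_pitch, residual)


def nominal_grid(shape: tuple[int, int], n_rows: int, n_cols: int) -> GridFit:
    """Centred lattice with one-pitch margins: the fallback for plates with
    no detectable signal (e.g. a fully failed mating), where quantification
    must still emit one measurement per expected spot."""
    py = shape[0] / (n_rows + 1)
    px = shape[1] / (n_cols + 1)
    oy = (shape[0] - 1) / 2.0 - py * (n_rows - 1) / 2.0
    ox = (shape[1] - 1) / 2.0 - px * (n_cols - 1) / 2.0
    centers = np.zeros((n_rows, n_cols, 2))
    centers[..., 0] = oy + py * np.arange(n_rows)[:, None]
    centers[..., 1] = ox + px * np.arange(n_cols)[None, :]
    return GridFit(n_rows, n_cols, centers, 0.5 * (py + px), float("nan"))


def _spot_windows(grid: GridFit, shape: tuple[int, int]):
    """Yield (r, c, window-slices, disc mask, annulus mask) per spot."""
    half = int(np.floor(grid.pitch / 2.0))
    r_spot = 0.45 * grid.pitch
    r_bg = 0.52 * grid.pitch  # background from window corners, clear of shoulders
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            cy, cx = grid.centers[r, c]
            y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
            x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
            y0c, x0c = max(y0, 0), max(x0, 0)
            y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            d = np.hypot(yy - cy, xx - cx)
            disc = d <= r_spot
            annulus = d > r_bg
            if not annulus.any():
                annulus = ~disc
            yield r, c, (slice(y0c, y1c), slice(x0c, x1c)), disc, annulus


def measure_density(image: np.ndarray, grid: GridFit) -> pd.DataFrame:
    """Integrated above-background intensity per spot (columns row,col,raw_density).

    Background is the median of the annulus between the spot disc and the
    window edge, estimated per spot so smooth illumination gradients cancel
    locally.  Negative integrals clamp to 0: densities are physically
    non-negative.
    """
    img = np.asarray(image, dtype=float)
    records = []
    for r, c, sl, disc, annulus in _spot_windows(grid, img.shape):
        win = img[sl]
        bg = float(np.median(win[annulus])) if annulus.any() else float(np.median(win))
        raw = float(np.clip((win[disc] - bg).sum(), 0.0, None))
        records.append({"row": r + 1, "col": c + 1, "raw_density": raw})
    return pd.DataFrame.from_records(records)


def measure_area(
    image: np.ndarray, grid: GridFit, threshold: Optional[float] = None
) -> pd.DataFrame:
    """Colony area (foreground pixels) per spot window on a diploid plate.

    A single global automatic threshold (Otsu) is applied; per-window
    foreground pixel counts are the colony areas.  An explicit ``threshold``
    overrides Otsu.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        if np.ptp(img) <= 0:
            threshold = np.inf  # featureless plate: nothing is foreground
        else:
            threshold = float(threshold_otsu(img))
            # Otsu splits anything, including pure noise; require the
            # threshold to clear the background by > 3 robust SDs
            med = float(np.median(img))
            mad_sd = 1.4826 * float(np.median(np.abs(img - med)))
            if threshold <= med + 3.0 * mad_sd:
                threshold = np.inf
    fg = img > threshold
    records = []
    for r, c, sl, disc, annulus in _spot_windows(grid, img.shape):
        records.append(
            {"row": r + 1, "col": c + 1, "diploid_area": int(fg[sl].sum())}
        )
    return pd.DataFrame.from_records(records)


def minmax_normalize(values: Union[Sequence[float], np.ndarray]) -> np.ndarray:
    """Map values onto [0, 1] via (v − min) / (max − min).

    All-equal input maps to all 1.0 (every colony is as large as the largest).
    Empty input is a hard error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot min-max normalize an empty value set")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.ones_like(arr)
    return (arr - lo) / (hi - lo)


def normalize_densities(
    raw: pd.DataFrame,
    area_norm: pd.DataFrame,
    epsilon: float = 0.05,
) -> pd.DataFrame:
    """Divide test densities by normalized diploid areas of their source wells.

    ``raw`` has one row per 384-format test spot with columns
    ``plate,row,col,prey,raw_density``; ``area_norm`` one row per 96-format
    well with columns ``plate,row,col,diploid_area,area_norm``.  Each test
    spot is matched to its source well via the quadrant map.  Wells with
    ``area_norm < epsilon`` (mating failures, including the min-mapped
    colony whose normalized area is exactly 0) are flagged ``failed_mating``
    and get no normalized density.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    for col in ("plate", "row", "col", "prey", "raw_density"):
        if col not in raw.columns:
            raise ValueError(f"raw table missing column {col!r}")
    for col in ("plate", "row", "col", "diploid_area", "area_norm"):
        if col not in area_norm.columns:
            raise ValueError(f"area table missing column {col!r}")

    spots = raw.copy()
    spots["row96"] = (spots["row"] + 1) // 2
    spots["col96"] = (spots["col"] + 1) // 2
    merged = spots.merge(
        area_norm.rename(columns={"row": "row96", "col": "col96"}),
        on=["plate", "row96", "col96"],
        how="left",
        validate="many_to_one",
    )
    if merged["area_norm"].isna().any():
        missing = merged.loc[merged["area_norm"].isna(), ["plate", "row", "col"]]
        raise ValueError(
            f"{len(missing)} test spots have no matching diploid well, e.g. "
            f"{missing.iloc[0].to_dict()}"
        )
    # a well with no diploid colony at all failed mating even when the
    # min-max normalization degenerates (e.g. every colony absent)
    ok = (merged["area_norm"] >= epsilon) & (merged["diploid_area"] > 0)
    merged["qc_flag"] = np.where(ok, "ok", "failed_mating")
    merged["normalized_density"] = np.where(
        ok, merged["raw_density"] / merged["area_norm"].where(ok, 1.0), np.nan
    )
    return merged[
        [
            "plate",
            "row",
            "col",
            "prey",
            "raw_density",
            "diploid_area",
            "area_norm",
            "normalized_density",
            "qc_flag",
        ]
    ]
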