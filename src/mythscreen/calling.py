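"""Cutoff calibration and positive-interaction calling.

The screen's decision rule has two parts:

1. **Calibration.**  A density cutoff is set to the 25th percentile of the
   densities of colonies manually categorized as "weak" interactions
   (linear-interpolation quantile convention).  One cutoff is applied to the
   entire screen.
2. **Calling.**  A bait–prey pair is called positive when at least one half
   of the prey's technical-replicate spots have a density strictly greater
   than the cutoff (ties at the cutoff count as below).  The reported
   density per pair is the arithmetic mean over *all* its usable replicate
   spots, not only those above the cutoff.

Prey whose diploid colonies failed to mate have no usable spots and are
reported with a ``no_call`` status rather than as negatives: absence of a
diploid is not absence of an interaction.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .colony_quant import (
    LowSignalError,
    fit_grid,
    measure_area,
    measure_density,
    minmax_normalize,
    nominal_grid,
    normalize_densities,
)
from .layout import EMPTY, LibraryLayout, PlateAddress, prey_at

__all__ = ["calibrate_cutoff", "call_interactions", "run_screen", "quantify_screen"]


def calibrate_cutoff(labels: Union[pd.DataFrame, Iterable[tuple[float, str]]]) -> float:
    """Density cutoff: 25th percentile of the "weak"-labeled colony densities.

    ``labels`` is a DataFrame with columns ``density,label`` (labels among
    negative/weak/medium/strong) or an iterable of (density, label) pairs.
    Raises if no colony is labeled weak.
    """
    if not isinstance(labels, pd.DataFrame):
        labels = pd.DataFrame(list(labels), columns=["density", "label"])
    if "density" not in labels.columns or "label" not in labels.columns:
        raise ValueError("labels need columns 'density' and 'label'")
    weak = labels.loc[labels["label"] == "weak", "density"].to_numpy(dtype=float)
    if weak.size == 0:
        raise ValueError("cannot calibrate: no colonies labeled 'weak'")
    if np.any(weak < 0):
        raise ValueError("densities must be >= 0")
    return float(np.percentile(weak, 25.0, method="linear"))


def call_interactions(
    spots: pd.DataFrame,
    cutoff: float,
    bait: Optional[str] = None,
    density_col: str = "density",
) -> pd.DataFrame:
    """Per-prey positive/negative calls from replicate spot densities.

    ``spots`` has columns ``prey`` and the density column (optionally
    ``bait``).  A prey with densities [10, 12, 3, 1] at cutoff 7 has 2 of 4
    spots above and is positive; [7, 7, 7, 7] at cutoff 7 has none (strict
    inequality) and is negative.  Prey present with zero non-null densities
    are emitted with status ``no_call`` — never silently dropped.

    Returns columns ``bait?, prey, n_spots, n_above, mean_density, positive,
    status``.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if "prey" not in spots.columns or density_col not in spots.columns:
        raise ValueError(f"spots need columns 'prey' and {density_col!r}")
    keys = ["bait", "prey"] if "bait" in spots.columns else ["prey"]
    records = []
    for key, grp in spots.groupby(keys, sort=True):
        dens = grp[density_col].to_numpy(dtype=float)
        dens = dens[~np.isnan(dens)]
        n = dens.size
        if n == 0:
            rec = dict(
                n_spots=0,
                n_above=0,
                mean_density=np.nan,
                positive=False,
                status="no_call",
            )
        else:
            n_above = int((dens > cutoff).sum())
            rec = dict(
                n_spots=n,
                n_above=n_above,
                mean_density=float(dens.mean()),
                positive=bool(2 * n_above >= n),
                status="ok",
            )
        if len(keys) == 2:
            rec = {"bait": key[0], "prey": key[1], **rec}
        else:
            rec = {"prey": key if not isinstance(key, tuple) else key[0], **rec}
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if bait is not None and "bait" not in out.columns:
        out.insert(0, "bait", bait)
    return out


def quantify_screen(
    test_images: Sequence[np.ndarray],
    diploid_images: Sequence[np.ndarray],
    layout: LibraryLayout,
    epsilon: float = 0.05,
) -> pd.DataFrame:
    """Image stages of the pipeline: grids → densities/areas → normalization.

    One diploid (96-format) and one test (384-format) image per library
    plate.  Diploid areas are min–max normalized over the whole screen (all
    plates of one bait pooled — one normalization per screen), then each
    test density is divided by its source well's normalized area.  Returns
    the per-spot table with columns ``plate,row,col,prey,raw_density,
    diploid_area,area_norm,normalized_density,qc_flag``.
    """
    if len(test_images) != len(diploid_images):
        raise ValueError("need one diploid image per test image")
    if len(test_images) != layout.n_plates:
        raise ValueError(
            f"layout spans {layout.n_plates} plates but {len(test_images)} image pairs given"
        )
    def _grid(img: np.ndarray, n_rows: int, n_cols: int):
        try:
            return fit_grid(img, n_rows, n_cols)
        except LowSignalError:
            # nothing grew on this plate; still measure every expected spot
            return nominal_grid(img.shape, n_rows, n_cols)

    area_tabs = []
    raw_tabs = []
    for i, (dip_img, test_img) in enumerate(zip(diploid_images, test_images), start=1):
        areas = measure_area(dip_img, _grid(dip_img, 8, 12))
        areas.insert(0, "plate", i)
        area_tabs.append(areas)
        raws = measure_density(test_img, _grid(test_img, 16, 24))
        raws.insert(0, "plate", i)
        raw_tabs.append(raws)
    areas = pd.concat(area_tabs, ignore_index=True)
    raws = pd.concat(raw_tabs, ignore_index=True)

    # keep only occupied wells; unoccupied positions carry no prey
    def _prey96(rec) -> str:
        return prey_at(
            layout, PlateAddress(int(rec.plate), int(rec.row), int(rec.col), format=96)
        )

    areas["prey"] = [ _prey96(rec) for rec in areas.itertuples() ]
    areas = areas[areas["prey"] != EMPTY].drop(columns="prey").reset_index(drop=True)
    areas["area_norm"] = minmax_normalize(areas["diploid_area"].to_numpy())

    def _prey384(rec) -> str:
        return prey_at(
            layout, PlateAddress(int(rec.plate), int(rec.row), int(rec.col), format=384)
        )

    raws["prey"] = [ _prey384(rec) for rec in raws.itertuples() ]
    raws = raws[raws["prey"] != EMPTY].reset_index(drop=True)

    return normalize_densities(raws, areas, epsilon=epsilon)


def run_screen(
    test_images: Sequence[np.ndarray],
    diploid_images: Sequence[np.ndarray],
    layout: LibraryLayout,
    labels: Optional[pd.DataFrame] = None,
    cutoff: Optional[float] = None,
    bait: str = "bait",
    epsilon: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Full screen: images → per-spot table → calibrated cutoff → calls.

    Exactly one of ``labels`` (manually categorized colony densities, used
    to calibrate the cutoff) or ``cutoff`` must be given.  Returns
    ``(interactome, spots, cutoff)`` where ``interactome`` has one row per
    prey (columns ``bait,prey,n_spots,n_above,mean_density,positive,status``)
    and ``spots`` is the per-spot measurement table.  Deterministic for
    fixed inputs.
    """
    if (labels is None) == (cutoff is None):
        raise ValueError("pass exactly one of labels= or cutoff=")
    spots = quantify_screen(test_images, diploid_images, layout, epsilon=epsilon)
    if cutoff is None:
        cutoff = calibrate_cutoff(labels)
    calls = call_interactions(
        spots, cutoff, bait=bait, density_col="normalized_density"
    )
    return calls, spots, float(cutoff)
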