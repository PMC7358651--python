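"""Climatic-suitability trajectories across epochs and range-area change.

Niche-model projections give one suitability surface (values in [0, 1]) per
epoch: Last Interglacial, Last Glacial Maximum, mid-Holocene, present.  For
each sampled population the pipeline draws jittered replicate localities
around the sampling coordinate (100 replicates within a 0.08-degree square
by default, compensating for single-grid-cell bias), extracts the
suitability value of the containing cell for every epoch, and summarizes
each epoch's replicate sample with the half-sample mode, a robust mode
estimator.  Suitable range area per epoch, latitude-corrected and relative
to the present, quantifies expansion and contraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import Raster

__all__ = [
    "SuitabilitySeries",
    "RangeChange",
    "jitter_localities",
    "extract_suitability",
    "half_sample_mode",
    "range_change",
    "check_raster_set",
]

EPOCH_ORDER = ("LIG", "LGM", "MH", "PRE")


def check_raster_set(rasters: dict[str, Raster]) -> None:
    """All epochs must share one grid geometry; values in [0,1] or nodata."""
    items = list(rasters.items())
    ref_name, ref = items[0]
    for name, r in items[1:]:
        if not ref.same_geometry(r):
            raise ValueError(f"raster geometry mismatch: {ref_name} vs {name}")
    for name, r in items:
        valid = r.data[~np.isclose(r.data, r.nodata)]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError(f"raster {name}: suitability outside [0, 1]")


def jitter_localities(
    coords: dict[str, tuple[float, float]],
    n_reps: int = 100,
    half_width: float = 0.08,
    seed: int | None = None,
    extent_raster: Raster | None = None,
    max_attempts: int = 1000,
) -> dict[str, np.ndarray]:
    """Replicate localities jittered uniformly within a square buffer.

    Each replicate is drawn uniformly from the square of side
    ``half_width`` degrees centered on the sampling locality.  When
    ``extent_raster`` is given, replicates falling outside its extent are
    resampled (error after ``max_attempts`` failures).  Returns, per
    population, an (n_reps, 2) array of (lat, lon).
    """
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, (lat, lon) in coords.items():
        if extent_raster is not None and not extent_raster.contains(lat, lon):
            raise ValueError(f"locality {name} outside raster extent")
        reps = np.empty((n_reps, 2))
        for i in range(n_reps):
            for attempt in range(max_attempts):
                dlat, dlon = rng.uniform(-half_width / 2, half_width / 2, size=2)
                cand = (lat + dlat, lon + dlon)
                if extent_raster is None or extent_raster.contains(*cand):
                    reps[i] = cand
                    break
            else:
                raise ValueError(
                    f"could not place replicate for {name} inside extent "
                    f"after {max_attempts} attempts"
                )
        out[name] = reps
    return out


@dataclass
class SuitabilitySeries:
    """Per-population suitability samples and half-sample-mode summaries."""

    values: pd.DataFrame  # columns: population, epoch, replicate, value
    hsm: pd.DataFrame  # index population, columns epochs
    n_dropped_nodata: int = 0

    def write_values_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_hsm_tsv(self, path: str | Path) -> None:
        self.hsm.to_csv(path, sep="\t", float_format="%.6g")


def extract_suitability(
    rasters: dict[str, Raster],
    replicates: dict[str, np.ndarray],
) -> SuitabilitySeries:
    """Nearest-cell suitability per replicate per epoch, with HSM summaries.

    Nodata cells are excluded (count reported); a population whose
    replicates all fall on nodata in some epoch is an error.  The result is
    independent of epoch ordering.
    """
    check_raster_set(rasters)
    rows = []
    dropped = 0
    for pop, reps in replicates.items():
        for epoch, raster in rasters.items():
            for i, (lat, lon) in enumerate(reps):
                value = raster.sample_nearest(lat, lon)
                if np.isnan(value):
                    dropped += 1
                    continue
                rows.append(
                    {"population": pop, "epoch": epoch, "replicate": i, "value": value}
                )
    values = pd.DataFrame(rows)
    hsm_rows = {}
    for pop in replicates:
        hsm_rows[pop] = {}
        for epoch in rasters:
            sample = values.query("population == @pop and epoch == @epoch")["value"]
            if sample.empty:
                raise ValueError(f"all replicates on nodata: {pop} / {epoch}")
            hsm_rows[pop][epoch] = half_sample_mode(sample.to_numpy())
    hsm = pd.DataFrame(hsm_rows).T[list(rasters)]
    hsm.index.name = "population"
    return SuitabilitySeries(values, hsm, dropped)


def half_sample_mode(values) -> float:
    """Robust mode by recursive halving of the sorted sample.

    Repeatedly keep the contiguous half (ceil(k/2) points) of the sorted
    sample with the smallest range, breaking ties toward the lower-index
    window, until at most two points remain; return their mean.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    while x.size > 2:
        w = int(np.ceil(x.size / 2))
        ranges = x[w - 1 :] - x[: x.size - w + 1]
        start = int(np.argmin(ranges))  # argmin takes the first minimum
        x = x[start : start + w]
    return float(x.mean())


@dataclass
class RangeChange:
    epoch: str
    reference: str
    ratio_percent: float
    threshold: float
    area_epoch_km2: float
    area_reference_km2: float


_KM_PER_DEG = 111.195  # mean earth-surface km per degree of great circle


def _suitable_area_km2(raster: Raster, threshold: float) -> float:
    """Latitude-corrected area of cells with suitability >= threshold."""
    valid = ~np.isclose(raster.data, raster.nodata)
    mask = valid & (raster.data >= threshold)
    cell_deg = raster.cellsize
    lat_weights = np.cos(np.radians(raster.cell_latitudes()))
    per_row = mask.sum(axis=1) * lat_weights
    return float(per_row.sum() * (cell_deg * _KM_PER_DEG) ** 2)


def range_change(
    rasters: dict[str, Raster],
    threshold: float,
    epoch: str,
    reference: str = "PRE",
) -> RangeChange:
    """Suitable-area ratio of an epoch relative to the reference epoch.

    Area sums latitude-corrected (cos-weighted) cell areas with suitability
    at or above the threshold; the ratio is in percent (100 = identical
    extent).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    for name in (epoch, reference):
        if name not in rasters:
            raise KeyError(f"missing epoch raster: {name}")
    check_raster_set({epoch: rasters[epoch], reference: rasters[reference]})
    area_e = _suitable_area_km2(rasters[epoch], threshold)
    area_r = _suitable_area_km2(rasters[reference], threshold)
    if area_r == 0:
        raise ValueError("reference epoch has zero suitable area")
    return RangeChange(
        epoch, reference, 100.0 * area_e / area_r, threshold, area_e, area_r
    )
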