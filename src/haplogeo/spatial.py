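"""Spatial null models for haplotype distributions.

Two bespoke geographic tests for whether mitochondrial haplotypes are
spatially structured within a study area:

* **MCP test** -- the minimum convex polygon (100% MCP, i.e. convex hull)
  area over which a haplotype occurs, compared with a null distribution
  obtained by permuting the full haplotype-label vector across samples
  (holding both the haplotype frequencies and every site's sample count
  exactly fixed) and recomputing the focal area. A haplotype whose
  observed area falls below the null 2.5th percentile is significantly
  geographically localised; above the 97.5th, significantly more
  widespread than expected.
* **Richness test** -- the number of distinct haplotypes observed at each
  sampling location with at least ``min_site_n`` samples, against the
  same permutation null.

Coordinates are planar kilometres (e.g. national-grid easting/northing
divided by 1000); no geodesy is attempted. ``lonlat_to_km`` offers an
approximate equirectangular conversion for longitude/latitude input.

No multiple-testing correction is applied across haplotypes or sites; the
CI-exclusion rule is reported per label, and this choice is recorded in
the output metadata of the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely import MultiPoint

from .seqdata import HaplotypeTable

__all__ = [
    "SampleRecord",
    "MCPArea",
    "NullTestResult",
    "read_sample_metadata",
    "attach_haplotypes",
    "lonlat_to_km",
    "mcp_area",
    "group_rare_haplotypes",
    "mcp_null_test",
    "richness_null_test",
]

RARE_LABEL = "HX"


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual placed in space.

    Coordinates may be NaN for samples lacking location data; such samples
    are logged and excluded from the spatial tests.
    """

    sample_id: str
    haplotype_id: str
    site_id: str
    x_km: float
    y_km: float

    @property
    def has_coordinates(self) -> bool:
        return math.isfinite(self.x_km) and math.isfinite(self.y_km)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a `sample_id,site_id,x_km,y_km` CSV (header required)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str})
    required = {"sample_id", "site_id", "x_km", "y_km"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def attach_haplotypes(
    metadata: pd.DataFrame, table: HaplotypeTable
) -> list[SampleRecord]:
    """Join sample metadata to a haplotype table's assignments.

    Samples in the metadata without a haplotype call (e.g. dropped for
    missing data) are skipped with a warning.
    """
    assignment = table.sample_to_haplotype()
    records: list[SampleRecord] = []
    unmatched: list[str] = []
    for row in metadata.itertuples(index=False):
        hap = assignment.get(row.sample_id)
        if hap is None:
            unmatched.append(row.sample_id)
            continue
        records.append(
            SampleRecord(
                row.sample_id, hap, row.site_id, float(row.x_km), float(row.y_km)
            )
        )
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} metadata sample(s) without a haplotype call "
            f"skipped: {unmatched[:10]}{'...' if len(unmatched) > 10 else ''}",
            stacklevel=2,
        )
    return records


def lonlat_to_km(
    lon: Sequence[float], lat: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate planar km via equirectangular projection about the
    centroid. Adequate for study areas of a few hundred km."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = float(np.mean(lat))
    lon0 = float(np.mean(lon))
    r = 6371.0088
    x = np.radians(lon - lon0) * r * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * r
    return x, y


@dataclass(frozen=True)
class MCPArea:
    """Convex-hull area with a degeneracy flag (< 3 distinct
    non-collinear points -> area 0, degenerate)."""

    area: float
    degenerate: bool

    def __float__(self) -> float:
        return self.area


def _hull_area(xy: np.ndarray) -> float:
    # shapely's convex hull; Point/LineString hulls have zero area
    return float(MultiPoint(xy).convex_hull.area)


def mcp_area(points: Iterable[tuple[float, float]]) -> MCPArea:
    """100% minimum convex polygon area of a point set, in km^2."""
    xy = np.asarray(list(points), dtype=float)
    if xy.size == 0:
        raise ValueError("mcp_area requires at least one point")
    area = _hull_area(xy)
    return MCPArea(area, degenerate=area == 0.0)


def group_rare_haplotypes(
    records: Sequence[SampleRecord], min_count: int = 5
) -> list[SampleRecord]:
    """Relabel haplotypes observed fewer than `min_count` times as 'HX'.

    All records are retained, so rare samples still occupy their sites in
    the permutation null of the frequent haplotypes.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = pd.Series([r.haplotype_id for r in records]).value_counts()
    rare = set(counts[counts < min_count].index)
    return [
        SampleRecord(r.sample_id, RARE_LABEL, r.site_id, r.x_km, r.y_km)
        if r.haplotype_id in rare
        else r
        for r in records
    ]


@dataclass(frozen=True)
class NullTestResult:
    """Observed statistic against a permutation null distribution."""

    label: str
    observed: float
    null_mean: float
    ci_low: float
    ci_high: float
    n_reps: int
    significant_low: bool
    significant_high: bool
    seed: int

    @property
    def significant(self) -> bool:
        return self.significant_low or self.significant_high


def _spatial_arrays(
    records: Sequence[SampleRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Label array, coordinate array, site array for located samples,
    plus the number of coordinate-less samples excluded."""
    located = [r for r in records if r.has_coordinates]
    n_missing = len(records) - len(located)
    if n_missing:
        warnings.warn(
            f"{n_missing} sample(s) without coordinates excluded from the "
            "spatial null test",
            stacklevel=3,
        )
    labels = np.array([r.haplotype_id for r in located])
    xy = np.array([(r.x_km, r.y_km) for r in located])
    sites = np.array([r.site_id for r in located])
    return labels, xy, sites, n_missing


def _summarise(
    label: str, observed: float, null: np.ndarray, n_reps: int, seed: int
) -> NullTestResult:
    ci_low, ci_high = np.percentile(null, [2.5, 97.5])
    return NullTestResult(
        label=label,
        observed=float(observed),
        null_mean=float(np.mean(null)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_reps=n_reps,
        significant_low=bool(observed < ci_low),
        significant_high=bool(observed > ci_high),
        seed=seed,
    )


def mcp_null_test(
    records: Sequence[SampleRecord],
    focal_haplotype: str,
    n_reps: int = 1000,
    seed: int = 0,
    min_count: int = 5,
    method: str = "permute",
) -> NullTestResult:
    """Test whether a haplotype's MCP area departs from the permutation null.

    Each replicate reshuffles the complete haplotype-label vector across
    samples (``method="permute"``, frequencies preserved exactly;
    ``method="multinomial"`` resamples labels with replacement instead)
    and recomputes the focal haplotype's hull area. Degenerate replicate
    hulls (area 0) are retained in the null distribution.
    """
    if method not in ("permute", "multinomial"):
        raise ValueError(f"unknown method: {method}")
    labels, xy, _, _ = _spatial_arrays(records)
    focal_mask = labels == focal_haplotype
    n_focal = int(focal_mask.sum())
    if n_focal < min_count:
        raise ValueError(
            f"focal haplotype '{focal_haplotype}' has {n_focal} located "
            f"samples (< {min_count}); group rare haplotypes first "
            "(see group_rare_haplotypes)"
        )
    observed = _hull_area(xy[focal_mask])
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    n = len(labels)
    for r in range(n_reps):
        if method == "permute":
            shuffled = labels[rng.permutation(n)]
        else:
            shuffled = labels[rng.integers(0, n, size=n)]
        null[r] = _hull_area(xy[shuffled == focal_haplotype])
    return _summarise(focal_haplotype, observed, null, n_reps, seed)


def richness_null_test(
    records: Sequence[SampleRecord],
    min_site_n: int = 3,
    n_reps: int = 1000,
    seed: int = 0,
) -> list[NullTestResult]:
    """Per-site haplotype richness against the label-permutation null.

    Sites with at least ``min_site_n`` located samples qualify. All
    qualifying sites share the same permutation in each replicate, exactly
    as in :func:`mcp_null_test`.
    """
    if min_site_n < 1:
        raise ValueError("min_site_n must be >= 1")
    labels, _, sites, _ = _spatial_arrays(records)
    site_ids, site_index = np.unique(sites, return_inverse=True)
    site_sizes = np.bincount(site_index)
    qualifying = [i for i in range(len(site_ids)) if site_sizes[i] >= min_site_n]
    if not qualifying:
        warnings.warn("no site meets the minimum sample count", stacklevel=2)
        return []

    def site_richness(lab: np.ndarray, site: int) -> int:
        return len(set(lab[site_index == site]))

    observed = {s: site_richness(labels, s) for s in qualifying}
    rng = np.random.default_rng(seed)
    n = len(labels)
    null = {s: np.empty(n_reps) for s in qualifying}
    for r in range(n_reps):
        shuffled = labels[rng.permutation(n)]
        for s in qualifying:
            null[s][r] = site_richness(shuffled, s)
    return [
        _summarise(str(site_ids[s]), observed[s], null[s], n_reps, seed)
        for s in qualifying
    ]


def results_to_dataframe(results: Sequence[NullTestResult]) -> pd.DataFrame:
    rows = [
        {
            "label": r.label,
            "observed": r.observed,
            "null_mean": r.null_mean,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "n_reps": r.n_reps,
            "significant": r.significant,
            "significant_low": r.significant_low,
            "significant_high": r.significant_high,
            "seed": r.seed,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "observed", "null_mean", "ci_low", "ci_high",
            "n_reps", "significant", "significant_low", "significant_high",
            "seed",
        ],
    )
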