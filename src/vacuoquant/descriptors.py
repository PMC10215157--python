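"""Per-region shape measures and per-image predictor vectors.

Five measures per segmented white region — area, perimeter, major axis
length (MAL), eccentricity, circularity — summarised per image as mean and
sample SD of each, giving the ten predictors used throughout the classifier
search (order: mean/SD of area, perimeter, MAL, eccentricity, circularity).

Definitions are pinned so values are comparable across runs:

* perimeter: chain-code length of the traced outer boundary (axial step 1,
  diagonal step sqrt(2)); the estimator is recorded in output metadata since
  circularity depends on it;
* MAL/eccentricity: from the ellipse with the same normalized second central
  moments as the pixel set, each coordinate variance corrected by +1/12
  (pixel as unit square), so single-file rows keep a nonzero minor axis;
* circularity: 4*pi*area / perimeter^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as _label

from .segmentation import LesionMask

PERIMETER_ESTIMATOR = "chain_code_sqrt2"

#: the ten predictor columns, in canonical order
PREDICTOR_COLUMNS = [
    "mean_area",
    "sd_area",
    "mean_perimeter",
    "sd_perimeter",
    "mean_mal",
    "sd_mal",
    "mean_eccentricity",
    "sd_eccentricity",
    "mean_circularity",
    "sd_circularity",
]

MEASURES = ["area", "perimeter", "mal", "eccentricity", "circularity"]


@dataclass(frozen=True)
class Region:
    """One 8-connected foreground component."""

    label_id: int
    coords: np.ndarray  # (N, 2) int array of (row, col)

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class RegionDescriptors:
    area: float
    perimeter: float
    mal: float
    eccentricity: float
    circularity: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.area, self.perimeter, self.mal, self.eccentricity, self.circularity)


@dataclass
class PredictorVector:
    """Ten per-image predictors plus bookkeeping flags."""

    values: np.ndarray  # length 10, PREDICTOR_COLUMNS order
    n_regions: int
    image_id: str = ""
    group: str = ""
    vd_present: bool = False
    no_lesions: bool = False
    single_region: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PREDICTOR_COLUMNS, (float(v) for v in self.values)))


def label_regions(mask: LesionMask | np.ndarray, connectivity: int = 8) -> list[Region]:
    """Partition foreground into components, in raster-scan order."""
    if isinstance(mask, LesionMask):
        arr = mask.mask
        connectivity = mask.params.connectivity
    else:
        arr = np.asarray(mask, dtype=bool)
    labelled = _label(arr, connectivity=1 if connectivity == 4 else 2)
    return [
        Region(label_id=i, coords=np.argwhere(labelled == i))
        for i in range(1, int(labelled.max()) + 1)
    ]


# 8 neighbours in clockwise order starting from West (Moore tracing order)
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_STEP = tuple(math.hypot(dr, dc) for dr, dc in _MOORE)


def chain_code_perimeter(coords: np.ndarray) -> float:
    """Chain-code length of the outer boundary traced through pixel centres.

    Moore-neighbour tracing; axial moves count 1, diagonal moves sqrt(2).
    The deterministic trace state is (pixel, backtrack neighbour); the walk
    eventually cycles and the cycle is the closed outer boundary, so the
    perimeter is the chain length accumulated around one full cycle.  A
    single pixel has no boundary path and returns 0.
    """
    coords = np.asarray(coords)
    if coords.shape[0] == 1:
        return 0.0
    rmin, cmin = coords.min(axis=0)
    patch = np.zeros(
        (coords[:, 0].max() - rmin + 3, coords[:, 1].max() - cmin + 3), dtype=bool
    )
    patch[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True

    start = tuple(int(v) for v in np.argwhere(patch)[0])  # uppermost-leftmost
    p = start
    backtrack = (start[0], start[1] - 1)  # its West neighbour is background
    seen: dict[tuple, float] = {}
    cum = 0.0
    while True:
        state = (p, backtrack)
        if state in seen:
            return cum - seen[state]
        seen[state] = cum
        i = _MOORE.index((backtrack[0] - p[0], backtrack[1] - p[1]))
        nxt = None
        for j in range(1, 9):
            d = (i + j) % 8
            q = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if patch[q]:
                nxt = q
                prev = (d - 1) % 8
                backtrack = (p[0] + _MOORE[prev][0], p[1] + _MOORE[prev][1])
                cum += _STEP[d]
                break
        if nxt is None:  # isolated pixel; unreachable for a connected N>1 set
            return 0.0
        p = nxt


def region_moments(coords: np.ndarray) -> tuple[float, float, float]:
    """Central second moments (var_r + 1/12, var_c + 1/12, cov_rc)."""
    coords = np.asarray(coords, dtype=np.float64)
    r = coords[:, 0]
    c = coords[:, 1]
    mu20 = r.var() + 1.0 / 12.0
    mu02 = c.var() + 1.0 / 12.0
    mu11 = ((r - r.mean()) * (c - c.mean())).mean()
    return mu20, mu02, mu11


def moment_ellipse(coords: np.ndarray) -> tuple[float, float, float]:
    """(major axis length, minor axis length, eccentricity) of the moment ellipse."""
    mu20, mu02, mu11 = region_moments(coords)
    common = mu20 + mu02
    delta = math.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11**2)
    mal = 2.0 * math.sqrt(2.0) * math.sqrt(common + delta)
    minor = 2.0 * math.sqrt(2.0) * math.sqrt(max(common - delta, 0.0))
    ecc = math.sqrt(max(1.0 - (minor / mal) ** 2, 0.0)) if mal > 0 else 0.0
    return mal, minor, ecc


def region_shape(region: Region | np.ndarray) -> RegionDescriptors:
    """The five shape measures of one region.

    Raises for regions whose traced boundary has zero length (single
    pixels): circularity is undefined there.
    """
    coords = region.coords if isinstance(region, Region) else np.asarray(region)
    area = float(coords.shape[0])
    if area < 1:
        raise ValueError("degenerate region: empty pixel set")
    perimeter = chain_code_perimeter(coords)
    if perimeter == 0.0:
        raise ValueError("degenerate region: zero-length boundary")
    mal, _minor, ecc = moment_ellipse(coords)
    circularity = 4.0 * math.pi * area / perimeter**2
    return RegionDescriptors(
        area=area, perimeter=perimeter, mal=mal, eccentricity=ecc, circularity=circularity
    )


def image_summary(
    regions: Sequence[RegionDescriptors], meta: Mapping[str, object] | None = None
) -> PredictorVector:
    """Mean and sample SD (n-1) of each measure, in canonical order.

    Zero regions -> all-zero vector flagged ``no_lesions``; one region ->
    SD components 0, flagged ``single_region``.
    """
    meta = dict(meta or {})
    n = len(regions)
    if n == 0:
        values = np.zeros(10)
    else:
        data = np.array([r.as_tuple() for r in regions])  # (n, 5)
        means = data.mean(axis=0)
        sds = data.std(axis=0, ddof=1) if n > 1 else np.zeros(5)
        values = np.empty(10)
        values[0::2] = means
        values[1::2] = sds
    return PredictorVector(
        values=values,
        n_regions=n,
        image_id=str(meta.get("image_id", "")),
        group=str(meta.get("group", "")),
        vd_present=bool(meta.get("vd_present", False)),
        no_lesions=(n == 0),
        single_region=(n == 1),
    )


def regions_table(per_image: Mapping[str, Sequence[RegionDescriptors]]) -> pd.DataFrame:
    """Long-format per-region table (``regions.csv`` schema)."""
    rows = []
    for image_id, descs in per_image.items():
        for rid, d in enumerate(descs):
            rows.append(
                {
                    "image_id": image_id,
                    "region_id": rid,
                    "area": d.area,
                    "perimeter": d.perimeter,
                    "mal": d.mal,
                    "eccentricity": d.eccentricity,
                    "circularity": d.circularity,
                }
            )
    return pd.DataFrame(
        rows, columns=["image_id", "region_id"] + MEASURES
    )


def predictors_table(vectors: Iterable[PredictorVector]) -> pd.DataFrame:
    """Wide per-image predictor table (``predictors.csv`` schema)."""
    rows = []
    for v in vectors:
        row = {
            "image_id": v.image_id,
            "group": v.group,
            "vd_present": v.vd_present,
            "n_regions": v.n_regions,
        }
        row.update(v.as_dict())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["image_id", "group", "vd_present", "n_regions"] + PREDICTOR_COLUMNS
    )


def describe_mask(mask: LesionMask | np.ndarray, meta: Mapping[str, object] | None = None):
    """Label a mask, measure all regions, summarise the image.

    Returns ``(list of RegionDescriptors, PredictorVector)``.
    """
    regions = label_regions(mask)
    descs = [region_shape(r) for r in regions]
    return descs, image_summary(descs, meta)
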