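"""Synthetic H&E-like liver micrographs with planted vacuolar lesions.

Real vacuolar degeneration (VD) shows up in hematoxylin–eosin sections as
bright, near-white "holes" in the pink hepatocyte cytoplasm.  This module
emulates that appearance well enough to exercise every downstream stage
(segmentation, shape description, group statistics, classifier search) with
known ground truth: each image carries the exact list of planted ellipses,
an optional central-vein region covered by an exclusion mask, and a
reproducible seed.

Group calibration defaults follow the pooled per-region shape statistics of
the four study arms (a no-drug CONTROL and three immunosuppressive-regimen
groups TMG, CMG, CEG): lesion areas are log-normal with group-specific
mean/SD, axis ratios reflect the groups' mean eccentricity (~0.78), and the
per-image probability that VD is present at all is 0.50 / 0.90 / 0.75 /
0.66 for CONTROL / TMG / CMG / CEG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.draw import ellipse as draw_ellipse
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

GROUPS = ("CONTROL", "TMG", "CMG", "CEG")

#: default per-group image counts of the study design (32 analysable livers)
DEFAULT_COUNTS = {"CONTROL": 6, "TMG": 10, "CMG": 9, "CEG": 7}

#: default canvas (rows, cols) — half the nominal 2572x1928 acquisition size
DEFAULT_CANVAS = (964, 1286)

#: smallest lesion area planted (px^2); just above the downstream <10 px filter
MIN_PLANT_AREA = 12.0

# Cosmetic palette (RGB).  Chosen so that in the green channel the tissue
# (background + nuclei) sits well below the white lesions after quantile
# contrast stretching; the palette carries no ground-truth information.
BACKGROUND_RGB = (228.0, 75.0, 160.0)
NUCLEUS_RGB = (70.0, 40.0, 90.0)
LESION_VALUE = 250.0  # all channels, before noise (>= 240 by contract)
NOISE_SD = 8.0


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one experimental group's lesions."""

    group_name: str
    lesion_count_range: tuple[int, int] = (5, 60)
    area_mean: float = 100.0          # px^2, pooled over regions
    area_sd: float = 50.0             # px^2
    axis_ratio_mean: float = 0.62     # minor/major, in (0, 1]
    axis_ratio_sd: float = 0.05
    boundary_roughness: float = 0.0   # 0 = perfect ellipse
    vd_presence_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.group_name not in GROUPS:
            raise ValueError(
                f"unknown group {self.group_name!r}; valid groups: {', '.join(GROUPS)}"
            )
        if not self.area_mean > 0:
            raise ValueError("area_mean must be > 0")
        if self.area_sd < 0:
            raise ValueError("area_sd must be >= 0")
        if not 0 < self.axis_ratio_mean <= 1:
            raise ValueError("axis_ratio_mean must be in (0, 1]")
        if self.boundary_roughness < 0:
            raise ValueError("boundary_roughness must be >= 0")
        if not 0 <= self.vd_presence_prob <= 1:
            raise ValueError("vd_presence_prob must be in [0, 1]")
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi):
            raise ValueError("lesion_count_range must be a non-decreasing pair >= 0")


def _axis_ratio_from_ecc(e: float) -> float:
    return math.sqrt(1.0 - e * e)


# Calibration defaults: pooled area mean/SD per group; axis ratio from the
# groups' mean eccentricity via q = sqrt(1 - e^2) with the ratio spread
# propagated from the eccentricity SD (delta method, dq/de = -e/q).
_TABLE_CALIBRATION = {
    # group: (area_mean, area_sd, ecc_mean, ecc_sd, vd_presence_prob)
    "CONTROL": (88.4908, 231.7392, 0.7883, 0.1525, 0.50),
    "TMG": (99.1502, 91.9057, 0.7769, 0.0056, 0.90),
    "CMG": (77.3647, 73.3464, 0.7762, 0.0065, 0.75),
    "CEG": (140.1070, 402.5104, 0.7751, 0.0063, 0.66),
}


def _default_profiles() -> dict[str, GroupProfile]:
    profiles = {}
    for g, (am, asd, em, esd, p) in _TABLE_CALIBRATION.items():
        q = _axis_ratio_from_ecc(em)
        q_sd = em / q * esd
        profiles[g] = GroupProfile(
            group_name=g,
            area_mean=am,
            area_sd=asd,
            axis_ratio_mean=q,
            axis_ratio_sd=q_sd,
            vd_presence_prob=p,
        )
    return profiles


DEFAULT_PROFILES = _default_profiles()


def generate_group_profile(
    group_name: str, overrides: Mapping[str, object] | None = None
) -> GroupProfile:
    """Return the packaged default profile for ``group_name``.

    Any profile field may be overridden through ``overrides``.
    """
    if group_name not in DEFAULT_PROFILES:
        raise ValueError(
            f"unknown group {group_name!r}; valid groups: {', '.join(GROUPS)}"
        )
    profile = DEFAULT_PROFILES[group_name]
    if overrides:
        profile = replace(profile, **dict(overrides))
    return profile


@dataclass(frozen=True)
class VacuoleSpec:
    """One planted lesion: an ellipse, optionally roughened radially."""

    center: tuple[float, float]  # (row, col)
    major_axis: float            # full length, px
    minor_axis: float
    orientation: float           # radians, CCW from the column axis
    roughness_seed: int = 0
    roughness: float = 0.0

    def __post_init__(self) -> None:
        if not self.minor_axis > 0 or self.major_axis < self.minor_axis:
            raise ValueError("require major_axis >= minor_axis > 0")

    @property
    def planted_area(self) -> float:
        """Nominal continuous area pi*a*b/4 of the ellipse."""
        return math.pi * self.major_axis * self.minor_axis / 4.0


@dataclass
class ImageRecord:
    """One micrograph with optional exclusion mask, labels and ground truth."""

    image: np.ndarray                      # uint8, H x W x 3
    exclusion_mask: np.ndarray | None      # bool, H x W; True = excluded
    group: str
    vd_present: bool
    truth: list[VacuoleSpec] | None
    seed: int
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.exclusion_mask is not None and (
            self.exclusion_mask.shape != self.image.shape[:2]
        ):
            raise ValueError("exclusion mask dimensions must equal image dimensions")


# ---------------------------------------------------------------------------
# lesion geometry sampling
# ---------------------------------------------------------------------------

def _lognormal_untruncated(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncated_lognormal_moments(mu: float, sigma: float, a: float) -> tuple[float, float]:
    """Mean and SD of a log-normal left-truncated at ``a`` (closed form)."""
    alpha = (math.log(a) - mu) / sigma
    p = stats.norm.sf(alpha)
    m1 = math.exp(mu + sigma**2 / 2.0) * stats.norm.sf(alpha - sigma) / p
    m2 = math.exp(2.0 * mu + 2.0 * sigma**2) * stats.norm.sf(alpha - 2.0 * sigma) / p
    var = m2 - m1 * m1
    return m1, math.sqrt(max(var, 0.0))


def lognormal_area_params(
    mean: float, sd: float, a_min: float = MIN_PLANT_AREA
) -> tuple[float, float]:
    """(mu, sigma) of the log-normal whose left-truncation at ``a_min`` has
    the requested mean and SD.

    Matching the truncated rather than the raw distribution keeps the pooled
    moments of the *plantable* lesions (those that survive the <10 px area
    filter downstream) on target even for heavy-tailed profiles.  Falls back
    to plain moment matching when the solver fails or truncation is
    irrelevant.
    """
    mu0, sigma0 = _lognormal_untruncated(mean, sd)
    if sd == 0 or stats.norm.sf((math.log(a_min) - mu0) / sigma0) > 0.999:
        return mu0, sigma0

    def equations(theta: np.ndarray) -> list[float]:
        mu, log_sigma = theta
        m, s = _truncated_lognormal_moments(mu, math.exp(log_sigma), a_min)
        return [m - mean, s - sd]

    sol, info, ier, _ = optimize.fsolve(
        equations, [mu0, math.log(sigma0)], full_output=True
    )
    if ier != 1 or not np.all(np.isfinite(sol)):
        return mu0, sigma0
    return float(sol[0]), float(math.exp(sol[1]))


def _sample_areas(profile: GroupProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    if profile.area_sd == 0:
        return np.full(n, profile.area_mean)
    mu, sigma = lognormal_area_params(profile.area_mean, profile.area_sd)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        draw = draw[draw >= MIN_PLANT_AREA]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _sample_axis_ratios(profile: GroupProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(profile.axis_ratio_mean, profile.axis_ratio_sd, size=n)
    return np.clip(q, 0.05, 1.0)


def sample_vacuoles(
    profile: GroupProfile,
    n_lesions: int,
    rng_seed: int,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    max_retries: int = 1000,
    keepout: np.ndarray | None = None,
) -> list[VacuoleSpec]:
    """Draw ``n_lesions`` non-overlapping lesion specs inside ``canvas``.

    Areas follow the profile's (truncated) log-normal; axis ratios a clipped
    normal; orientations are uniform.  Placement uses rejection sampling with
    a conservative circumscribed-circle overlap test; after ``max_retries``
    failed placements for any lesion a ValueError is raised.  ``keepout``
    optionally marks canvas pixels (e.g. a vein) lesions must avoid.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    if n_lesions == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    areas = _sample_areas(profile, n_lesions, rng)
    ratios = _sample_axis_ratios(profile, n_lesions, rng)
    H, W = canvas
    gap = 3.0
    specs: list[VacuoleSpec] = []
    radii: list[float] = []
    centers: list[tuple[float, float]] = []
    for i in range(n_lesions):
        major = math.sqrt(4.0 * areas[i] / (math.pi * ratios[i]))
        minor = ratios[i] * major
        theta = rng.uniform(0.0, math.pi)
        r_out = major / 2.0 * (1.0 + profile.boundary_roughness) + 1.0
        if 2.0 * (r_out + gap) >= min(H, W):
            raise ValueError(
                f"canvas {canvas} too small for a lesion of major axis {major:.1f} px"
            )
        placed = False
        for _ in range(max_retries):
            cr = rng.uniform(r_out + gap, H - 1 - r_out - gap)
            cc = rng.uniform(r_out + gap, W - 1 - r_out - gap)
            ok = all(
                math.hypot(cr - pr, cc - pc) > r_out + prad + gap
                for (pr, pc), prad in zip(centers, radii)
            )
            if ok and keepout is not None:
                rr0 = max(0, int(cr - r_out - gap))
                rr1 = min(H, int(cr + r_out + gap) + 1)
                cc0 = max(0, int(cc - r_out - gap))
                cc1 = min(W, int(cc + r_out + gap) + 1)
                ok = not keepout[rr0:rr1, cc0:cc1].any()
            if ok:
                specs.append(
                    VacuoleSpec(
                        center=(cr, cc),
                        major_axis=major,
                        minor_axis=minor,
                        orientation=theta,
                        roughness_seed=int(rng.integers(0, 2**31 - 1)),
                        roughness=profile.boundary_roughness,
                    )
                )
                centers.append((cr, cc))
                radii.append(r_out)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place lesion {i + 1}/{n_lesions} on canvas {canvas} "
                f"after {max_retries} retries"
            )
    return specs


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def rasterize_vacuole(spec: VacuoleSpec, canvas: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the spec's pixels (pixel-centre-inside test)."""
    H, W = canvas
    a = spec.major_axis / 2.0
    b = spec.minor_axis / 2.0
    pad = a * (1.0 + spec.roughness) + 2.0
    cr, cc = spec.center
    r0, r1 = max(0, int(cr - pad)), min(H, int(cr + pad) + 1)
    c0, c1 = max(0, int(cc - pad)), min(W, int(cc + pad) + 1)
    rr, cols = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cols - cc
    cos_t, sin_t = math.cos(spec.orientation), math.sin(spec.orientation)
    # rotate into the ellipse frame (u along the major axis)
    u = dc * cos_t + dr * sin_t
    v = -dc * sin_t + dr * cos_t
    if spec.roughness == 0:
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:
        # radial perturbation by a few smooth harmonics, bounded by roughness
        h_rng = np.random.default_rng(spec.roughness_seed)
        ks = np.arange(2, 6)
        amp = h_rng.normal(size=ks.size)
        phase = h_rng.uniform(0, 2 * math.pi, size=ks.size)
        amp /= np.abs(amp).sum() or 1.0
        phi = np.arctan2(v, u)
        g = np.zeros_like(phi)
        for k, A, ph in zip(ks, amp, phase):
            g += A * np.cos(k * phi + ph)
        r_ell = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        rho = np.hypot(u, v)
        inside = rho <= r_ell * (1.0 + spec.roughness * g)
    mask = np.zeros((H, W), dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def _draw_nuclei(
    shade: np.ndarray, canvas: tuple[int, int], rng: np.random.Generator
) -> None:
    """Mark nucleus pixels in ``shade`` (bool scratch mask), ~5% coverage."""
    H, W = canvas
    n = int(0.05 * H * W / 50.0)
    for _ in range(n):
        cr = rng.uniform(0, H - 1)
        cc = rng.uniform(0, W - 1)
        ra = rng.uniform(2.5, 5.0)
        rb = rng.uniform(0.6, 1.0) * ra
        theta = rng.uniform(0, math.pi)
        rr, cc_ = draw_ellipse(cr, cc, ra, rb, shape=(H, W), rotation=theta)
        shade[rr, cc_] = True


def _draw_speckles(
    canvas: tuple[int, int], forbidden: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sub-10-px bright speckles (image noise) on a coarse grid.

    The grid guarantees speckles never coalesce into a >= 10 px component and
    the ``forbidden`` mask keeps them clear of lesions and vein, so they are
    always (and only) removed by the small-region filter downstream.
    """
    H, W = canvas
    cell = 6
    mask = np.zeros((H, W), dtype=bool)
    shapes = (
        [(0, 0)],
        [(0, 0), (0, 1)],
        [(0, 0), (1, 0)],
        [(0, 0), (0, 1), (1, 0), (1, 1)],
        [(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)],
    )
    for gr in range(1, H // cell - 1):
        for gc in range(1, W // cell - 1):
            if rng.random() >= 0.30:
                continue
            cr = gr * cell + int(rng.integers(2, cell - 2))
            cc = gc * cell + int(rng.integers(2, cell - 2))
            if forbidden[cr, cc]:
                continue
            for dr, dc in shapes[int(rng.integers(0, len(shapes)))]:
                r, c = cr + dr, cc + dc
                if 0 <= r < H and 0 <= c < W and not forbidden[r, c]:
                    mask[r, c] = True
    return mask


def _place_vein(
    canvas: tuple[int, int],
    lesion_mask: np.ndarray,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> np.ndarray:
    """Boolean mask of a central-vein-like white region avoiding lesions."""
    H, W = canvas
    ra = rng.uniform(0.04, 0.07) * min(H, W)
    rb = rng.uniform(0.6, 0.9) * ra
    theta = rng.uniform(0, math.pi)
    pad = ra + 6
    for _ in range(max_retries):
        cr = rng.uniform(pad, H - 1 - pad)
        cc = rng.uniform(pad, W - 1 - pad)
        rr, cc_ = draw_ellipse(cr, cc, ra, rb, shape=(H, W), rotation=theta)
        vein = np.zeros((H, W), dtype=bool)
        vein[rr, cc_] = True
        grown = binary_dilation(vein, structure=disk(4))
        if not (grown & lesion_mask).any():
            return vein
    raise ValueError("could not place vein clear of lesions")


def render_image(
    specs: Sequence[VacuoleSpec],
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    with_vein: bool = False,
    rng_seed: int = 0,
    group: str = "CONTROL",
    vd_present: bool | None = None,
    noise_sd: float = NOISE_SD,
    image_id: str = "",
) -> ImageRecord:
    """Render lesion specs onto a synthetic H&E-like canvas.

    Vacuole and vein pixels are near-white (all channels 250 before noise);
    the background is pink-textured with darker nucleus blobs and sparse
    sub-10-px bright speckles; per-channel Gaussian noise (SD ``noise_sd``)
    is added last.  If ``with_vein``, a large white region is drawn and fully
    covered by the returned exclusion mask.
    """
    H, W = canvas
    rng = np.random.default_rng(rng_seed)

    lesion_mask = np.zeros((H, W), dtype=bool)
    for spec in specs:
        m = rasterize_vacuole(spec, canvas)
        if (m & lesion_mask).any():
            raise ValueError("lesion specs overlap on the canvas")
        lesion_mask |= m

    nuclei = np.zeros((H, W), dtype=bool)
    _draw_nuclei(nuclei, canvas, rng)

    vein = None
    exclusion = None
    if with_vein:
        vein = _place_vein(canvas, lesion_mask, rng)
        exclusion = binary_dilation(vein, structure=disk(3))

    white = lesion_mask if vein is None else (lesion_mask | vein)
    forbidden = binary_dilation(white, structure=disk(4))
    speckles = _draw_speckles(canvas, forbidden, rng)

    img = np.empty((H, W, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = BACKGROUND_RGB[ch]
        img[..., ch][nuclei] = NUCLEUS_RGB[ch]
    img[speckles] = LESION_VALUE
    img[white] = LESION_VALUE
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return ImageRecord(
        image=img,
        exclusion_mask=exclusion,
        group=group,
        vd_present=len(specs) > 0 if vd_present is None else vd_present,
        truth=list(specs),
        seed=int(rng_seed),
        image_id=image_id,
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Configuration for :func:`make_dataset`."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    canvas: tuple[int, int] = DEFAULT_CANVAS
    with_vein: bool = True
    noise_sd: float = NOISE_SD
    profile_overrides: dict[str, dict[str, object]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "DatasetConfig":
        kwargs: dict[str, object] = {}
        if "counts" in d:
            kwargs["counts"] = {str(k): int(v) for k, v in dict(d["counts"]).items()}
        if "canvas" in d:
            kwargs["canvas"] = tuple(int(v) for v in d["canvas"])
        if "with_vein" in d:
            kwargs["with_vein"] = bool(d["with_vein"])
        if "noise_sd" in d:
            kwargs["noise_sd"] = float(d["noise_sd"])
        if "profiles" in d:
            kwargs["profile_overrides"] = {
                str(g): dict(ov) for g, ov in dict(d["profiles"]).items()
            }
        return cls(**kwargs)


def _child_seeds(master_seed: int, group_index: int, image_index: int) -> np.ndarray:
    """Three stable 31-bit child seeds for one image.

    Keyed on (master seed, group, image index) so adding images or groups
    never perturbs previously generated ones.
    """
    ss = np.random.SeedSequence([int(master_seed), group_index, image_index])
    return ss.generate_state(3) % (2**31)


def make_dataset(
    config: DatasetConfig | Mapping[str, object] | None,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[ImageRecord], pd.DataFrame, pd.DataFrame]:
    """Generate a full labelled dataset, optionally writing it to disk.

    Returns ``(records, manifest, truth)``.  When ``out_dir`` is given the
    images (PNG), exclusion masks (PNG, 0/255), ``manifest.csv``
    (path,mask_path,group,vd_present,seed) and ``truth.csv`` are written
    there, byte-reproducibly for a fixed (config, master_seed).
    """
    if config is None:
        config = DatasetConfig()
    elif not isinstance(config, DatasetConfig):
        config = DatasetConfig.from_dict(config)

    records: list[ImageRecord] = []
    manifest_rows = []
    truth_rows = []
    for gi, group in enumerate(GROUPS):
        n_images = config.counts.get(group, 0)
        profile = generate_group_profile(group, config.profile_overrides.get(group))
        for ii in range(n_images):
            s_decide, s_sample, s_render = (int(s) for s in _child_seeds(master_seed, gi, ii))
            rng = np.random.default_rng(s_decide)
            vd_present = bool(rng.random() < profile.vd_presence_prob)
            if vd_present:
                lo, hi = profile.lesion_count_range
                n_lesions = int(rng.integers(lo, hi + 1))
            else:
                n_lesions = 0
            specs = sample_vacuoles(profile, n_lesions, s_sample, canvas=config.canvas)
            image_id = f"{group}_{ii:03d}"
            record = render_image(
                specs,
                canvas=config.canvas,
                with_vein=config.with_vein,
                rng_seed=s_render,
                group=group,
                vd_present=vd_present,
                noise_sd=config.noise_sd,
                image_id=image_id,
            )
            records.append(record)
            manifest_rows.append(
                {
                    "path": f"images/{image_id}.png",
                    "mask_path": f"masks/{image_id}_mask.png"
                    if record.exclusion_mask is not None
                    else "",
                    "group": group,
                    "vd_present": vd_present,
                    "seed": s_render,
                }
            )
            for li, spec in enumerate(specs):
                truth_rows.append(
                    {
                        "image_id": image_id,
                        "lesion_id": li,
                        "center_r": spec.center[0],
                        "center_c": spec.center[1],
                        "major": spec.major_axis,
                        "minor": spec.minor_axis,
                        "orientation": spec.orientation,
                        "planted_area": spec.planted_area,
                    }
                )

    manifest = pd.DataFrame(
        manifest_rows, columns=["path", "mask_path", "group", "vd_present", "seed"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "image_id",
            "lesion_id",
            "center_r",
            "center_c",
            "major",
            "minor",
            "orientation",
            "planted_area",
        ],
    )

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for record, row in zip(records, manifest_rows):
            iio.imwrite(out / row["path"], record.image, extension=".png")
            if record.exclusion_mask is not None:
                iio.imwrite(
                    out / row["mask_path"],
                    (record.exclusion_mask.astype(np.uint8) * 255),
                    extension=".png",
                )
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)

    return records, manifest, truth


def load_manifest(manifest_path: str | Path) -> list[ImageRecord]:
    """Load image records listed in a manifest CSV (synthetic or user data)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    records = []
    for _, row in manifest.iterrows():
        img = np.asarray(iio.imread(root / row["path"]))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3]
        mask = None
        if row.get("mask_path", ""):
            mask = np.asarray(iio.imread(root / row["mask_path"])) > 0
            if mask.ndim == 3:
                mask = mask[..., 0]
        vd = row["vd_present"]
        records.append(
            ImageRecord(
                image=img.astype(np.uint8),
                exclusion_mask=mask,
                group=str(row["group"]),
                vd_present=str(vd).lower() in ("true", "1"),
                truth=None,
                seed=int(row.get("seed", 0) or 0),
                image_id=Path(str(row["path"])).stem,
            )
        )
    return records
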