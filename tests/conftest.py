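import numpy as np
import pandas as pd
import pytest

import vacuoquant as vq
from vacuoquant.pipeline import describe_records, segment_records
from vacuoquant.segmentation import SegmentationParams
from vacuoquant.synth import rasterize_vacuole


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shaped default dataset (6/10/9/7 images), fixed seed."""
    records, manifest, truth = vq.make_dataset(None, 1234)
    return records, manifest, truth


@pytest.fixture(scope="session")
def region_rich_dataset():
    """A lesion-dense dataset giving ~1600 (CONTROL/CEG) and ~600 (TMG/CMG)
    regions per group, enough to resolve the heavy-tailed area profiles.

    Returns (regions table, manifest, planted rasterized mean area/group).
    """
    layout = {"CONTROL": (3000, 40), "TMG": (4000, 15), "CMG": (5000, 15), "CEG": (6000, 40)}
    records, rows, planted_mean = [], [], {}
    for g, (base, n_img) in layout.items():
        profile = vq.generate_group_profile(g, {"lesion_count_range": (40, 40)})
        planted = []
        for i in range(n_img):
            specs = vq.sample_vacuoles(profile, 40, base + i, canvas=(720, 720))
            rec = vq.render_image(
                specs, canvas=(720, 720), rng_seed=base + 500 + i, group=g,
                image_id=f"{g}_{i:03d}",
            )
            records.append(rec)
            rows.append({"image_id": rec.image_id, "group": g, "vd_present": True})
            planted += [int(rasterize_vacuole(s, (720, 720)).sum()) for s in specs]
        planted_mean[g] = float(np.mean(planted))
    masks = segment_records(records, SegmentationParams())
    regions, _ = describe_records(records, masks)
    return regions, pd.DataFrame(rows), planted_mean


def _blob_at_scale(params, scale: float, size: int) -> np.ndarray:
    from skimage.draw import disk as draw_disk
    from skimage.measure import label

    canvas = np.zeros((size, size), dtype=bool)
    centre = size / 2
    for dr, dc, r in params:
        rr, cc = draw_disk(
            (centre + dr * scale, centre + dc * scale), r * scale, shape=(size, size)
        )
        canvas[rr, cc] = True
    labelled = label(canvas, connectivity=2)
    # keep the largest component to guarantee connectivity
    counts = np.bincount(labelled.ravel())
    counts[0] = 0
    return np.argwhere(labelled == counts.argmax())


def random_blob(rng: np.random.Generator, n_disks: int = 4, size: int = 64) -> np.ndarray:
    """Random connected blob as a union of overlapping disks; (N, 2) coords."""
    params = [
        (rng.uniform(-6, 6), rng.uniform(-6, 6), rng.uniform(4, 9))
        for _ in range(n_disks)
    ]
    return _blob_at_scale(params, 1.0, size)


def random_blob_pair(rng: np.random.Generator, n_disks: int = 4):
    """The same random disk-union geometry digitized at scale 1 and scale 2."""
    params = [
        (rng.uniform(-6, 6), rng.uniform(-6, 6), rng.uniform(4, 9))
        for _ in range(n_disks)
    ]
    return _blob_at_scale(params, 1.0, 64), _blob_at_scale(params, 2.0, 128)
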