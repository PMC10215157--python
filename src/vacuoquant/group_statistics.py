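"""Group-level distribution statistics over pooled lesion regions.

Per-group "merged" estimators pool every region across a group's images
(not per-image means): a 4-group x 10-column table of mean and sample SD of
the five shape measures.  Anderson–Darling normality checks justify (or
rule out) parametric modelling of the pooled distributions, and two-sample
Kolmogorov–Smirnov tests compare the control group with each treatment
group measure by measure.  No multiple-testing correction is applied; the
outputs carry raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

from .descriptors import MEASURES
from .synth import GROUPS

DEFAULT_PAIRS = (("CONTROL", "TMG"), ("CONTROL", "CMG"), ("CONTROL", "CEG"))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test: str
    n_x: int
    n_y: int = 0


def _image_groups(manifest: pd.DataFrame) -> pd.DataFrame:
    """Normalize a manifest to (image_id, group)."""
    m = manifest.copy()
    if "image_id" not in m.columns:
        m["image_id"] = m["path"].map(lambda p: Path(str(p)).stem)
    return m[["image_id", "group"]]


def pooled_group_estimators(
    regions: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Mean and sample SD of each measure over all regions pooled per group.

    Returns a 4 x 10 table (rows CONTROL, TMG, CMG, CEG; columns mean/SD of
    area, perimeter, MAL, eccentricity, circularity).  A group with no
    regions yields an all-NaN row with a warning.
    """
    merged = regions.merge(_image_groups(manifest), on="image_id", how="left")
    columns = []
    for m in MEASURES:
        columns += [f"mean_{m}", f"sd_{m}"]
    rows = {}
    present_groups = [g for g in GROUPS if g in set(manifest["group"])]
    for g in present_groups:
        sub = merged[merged["group"] == g]
        if len(sub) == 0:
            warnings.warn(f"group {g} has no regions; emitting NaN row")
            rows[g] = [np.nan] * 10
            continue
        vals = []
        for m in MEASURES:
            x = sub[m].to_numpy(dtype=float)
            vals += [x.mean(), x.std(ddof=1) if len(x) > 1 else 0.0]
        rows[g] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    out.index.name = "group"
    return out


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum distance between the empirical CDFs; the p-value uses
    the asymptotic Kolmogorov distribution with effective sample size
    n_x*n_y/(n_x+n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires nonempty samples")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(max(res.pvalue, 0.0), 1.0)),
        test="ks_2samp",
        n_x=int(x.size),
        n_y=int(y.size),
    )


def anderson_darling_normality(x) -> TestResult:
    """Anderson–Darling test of normality with estimated mean and variance.

    The statistic reported is the small-sample-modified
    A*^2 = A^2 (1 + 0.75/n + 2.25/n^2); the p-value uses the standard
    approximation for the estimated-parameters case.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("Anderson–Darling normality test requires n >= 8")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    a2, p = normal_ad(x)
    a2_mod = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    return TestResult(
        statistic=float(a2_mod),
        p_value=float(min(max(p, 0.0), 1.0)),
        test="anderson_darling_normality",
        n_x=int(n),
    )


def distribution_tests(
    regions: pd.DataFrame,
    manifest: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
) -> pd.DataFrame:
    """KS comparisons of region-level measure distributions for group pairs.

    One row per (pair, measure): columns pair, measure, test, statistic,
    p_value, n_x, n_y.  Pairs with an empty side are skipped with a warning.
    """
    merged = regions.merge(_image_groups(manifest), on="image_id", how="left")
    rows = []
    for gx, gy in pairs:
        x_sub = merged[merged["group"] == gx]
        y_sub = merged[merged["group"] == gy]
        if len(x_sub) == 0 or len(y_sub) == 0:
            warnings.warn(f"pair {gx}-{gy}: a side has no regions; skipped")
            continue
        for m in MEASURES:
            res = ks_two_sample(x_sub[m], y_sub[m])
            rows.append(
                {
                    "pair": f"{gx}-{gy}",
                    "measure": m,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_x": res.n_x,
                    "n_y": res.n_y,
                }
            )
    return pd.DataFrame(
        rows, columns=["pair", "measure", "test", "statistic", "p_value", "n_x", "n_y"]
    )


def normality_tests(regions: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Anderson–Darling normality per (group, measure) on pooled regions."""
    merged = regions.merge(_image_groups(manifest), on="image_id", how="left")
    rows = []
    for g in GROUPS:
        sub = merged[merged["group"] == g]
        for m in MEASURES:
            x = sub[m].to_numpy(dtype=float)
            if x.size < 8 or np.ptp(x) == 0:
                continue
            res = anderson_darling_normality(x)
            rows.append(
                {
                    "group": g,
                    "measure": m,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n_x,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "measure", "test", "statistic", "p_value", "n"]
    )
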