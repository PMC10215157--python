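"""Exhaustive linear-classifier search over predictor subsets.

With ten per-image predictors there are 2^10 - 1 = 1023 non-empty subsets.
Each subset is scored with a pooled-covariance linear discriminant (Fisher
LDA with empirical class priors, lightly ridge-regularized for
solvability), by resubstitution accuracy by default (leave-one-out
optionally).  Five classification schemes are supported:

* ``ONE_VS_REST``  — each group against the merged remaining groups;
* ``COMMON_PREDICTORS`` — one shared subset scored by the average accuracy
  of the four one-vs-rest classifiers;
* ``PAIRED`` — CONTROL against each treatment group separately;
* ``VD_PRESENCE`` — all images merged, classified by presence of vacuolar
  degeneration;
* ``CONTROL_VS_MERGED`` — VD-present images only, CONTROL vs pooled
  treatment groups.

Reports list *all* subsets tied at the best (accuracy, minimal size) and
the Pareto front under (maximize accuracy, minimize subset size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import PREDICTOR_COLUMNS
from .synth import GROUPS

SCHEMES = ("ONE_VS_REST", "COMMON_PREDICTORS", "PAIRED", "VD_PRESENCE", "CONTROL_VS_MERGED")

MEAN_PREDICTORS = [c for c in PREDICTOR_COLUMNS if c.startswith("mean_")]
SD_PREDICTORS = [c for c in PREDICTOR_COLUMNS if c.startswith("sd_")]

RIDGE_LAMBDA = 1e-6


def enumerate_subsets(n_predictors: int) -> list[int]:
    """All non-empty subsets of ``n_predictors`` items as ascending bitmasks."""
    if not 1 <= n_predictors <= 20:
        raise ValueError("n_predictors must be in 1..20")
    return list(range(1, 2**n_predictors))


def subset_indices(bitmask: int) -> list[int]:
    return [i for i in range(bitmask.bit_length()) if bitmask >> i & 1]


@dataclass
class LinearModel:
    """Two-class pooled-covariance linear discriminant."""

    classes: tuple[str, str]           # order fixes the tie-break (first wins)
    means: np.ndarray                  # (2, p)
    cov_inv: np.ndarray                # (p, p)
    log_priors: np.ndarray             # (2,)
    subset_mask: int = 0

    @property
    def weights(self) -> np.ndarray:
        """Discriminant direction w = Sigma^-1 (mu_1 - mu_0)."""
        return self.cov_inv @ (self.means[1] - self.means[0])

    @property
    def intercept(self) -> float:
        m0, m1 = self.means
        return float(
            -0.5 * (m1 @ self.cov_inv @ m1 - m0 @ self.cov_inv @ m0)
            + self.log_priors[1]
            - self.log_priors[0]
        )

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"dimension mismatch: model has {self.means.shape[1]} features, "
                f"data has {X.shape[1]}"
            )
        out = np.empty((X.shape[0], 2))
        for k in range(2):
            mk = self.means[k]
            out[:, k] = X @ self.cov_inv @ mk - 0.5 * mk @ self.cov_inv @ mk + self.log_priors[k]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        idx = np.argmax(s, axis=1)  # ties -> first listed class
        return np.asarray(self.classes)[idx]


def fit_linear(
    X: np.ndarray, y: Sequence, classes: tuple[str, str] | None = None, subset_mask: int = 0
) -> LinearModel:
    """Fit a Fisher linear discriminant with pooled within-class covariance.

    The covariance is ridge-regularized by lambda * trace(Sigma)/p * I with
    lambda = 1e-6; a zero-trace (all-constant-feature) covariance falls back
    to the identity, reducing the rule to class priors and nearest means.
    Ties in the discriminant scores resolve to the class listed first.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y)
    if classes is None:
        classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError("fit_linear requires exactly two classes")
    n, p = X.shape
    means = np.empty((2, p))
    priors = np.empty(2)
    scatter = np.zeros((p, p))
    for k, cls in enumerate(classes):
        Xk = X[y == cls]
        if len(Xk) == 0:
            raise ValueError(f"class {cls!r} has no rows")
        means[k] = Xk.mean(axis=0)
        priors[k] = len(Xk) / n
        d = Xk - means[k]
        scatter += d.T @ d
    dof = max(n - 2, 1)
    cov = scatter / dof
    tr = np.trace(cov)
    if tr == 0:
        cov = np.eye(p)
    else:
        cov = cov + RIDGE_LAMBDA * (tr / p) * np.eye(p)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.pinv(cov)
    return LinearModel(
        classes=tuple(classes),
        means=means,
        cov_inv=cov_inv,
        log_priors=np.log(priors),
        subset_mask=subset_mask,
    )


def accuracy(model: LinearModel, X: np.ndarray, y: Sequence) -> float:
    """Resubstitution accuracy: fraction of rows predicted correctly."""
    y = np.asarray(y)
    return float(np.mean(model.predict(X) == y))


def loocv_accuracy(X: np.ndarray, y: Sequence, classes: tuple[str, str]) -> float:
    """Leave-one-out accuracy (refits n times)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = len(y)
    hits = 0
    for i in range(n):
        keep = np.arange(n) != i
        yi = y[keep]
        if len(set(yi)) < 2:
            continue
        m = fit_linear(X[keep], yi, classes)
        hits += int(m.predict(X[i : i + 1])[0] == y[i])
    return hits / n


@dataclass(frozen=True)
class BinaryProblem:
    """One two-class task extracted from the predictor table."""

    name: str
    X: np.ndarray
    y: np.ndarray
    classes: tuple[str, str]


@dataclass
class SearchResult:
    scheme: str
    problem: str
    bitmask: int
    n_predictors: int
    accuracy: float


def _problems_for_scheme(
    table: pd.DataFrame, scheme: str, feature_columns: Sequence[str]
) -> list[BinaryProblem]:
    X_all = table[list(feature_columns)].to_numpy(dtype=float)
    groups = table["group"].to_numpy()
    problems: list[BinaryProblem] = []
    if scheme in ("ONE_VS_REST", "COMMON_PREDICTORS"):
        for g in GROUPS:
            if (groups == g).sum() < 2 or (groups != g).sum() < 2:
                warnings.warn(f"{scheme}: class {g} or its complement has <2 rows; skipped")
                continue
            y = np.where(groups == g, g, "REST")
            problems.append(BinaryProblem(name=g, X=X_all, y=y, classes=(g, "REST")))
    elif scheme == "PAIRED":
        for g in ("TMG", "CMG", "CEG"):
            sel = (groups == "CONTROL") | (groups == g)
            if (groups == "CONTROL").sum() < 2 or (groups == g).sum() < 2:
                warnings.warn(f"PAIRED: CONTROL-{g} lacks rows; skipped")
                continue
            problems.append(
                BinaryProblem(
                    name=f"CONTROL-{g}", X=X_all[sel], y=groups[sel], classes=("CONTROL", g)
                )
            )
    elif scheme == "VD_PRESENCE":
        vd = np.where(table["vd_present"].to_numpy(dtype=bool), "VD", "NO_VD")
        if (vd == "VD").sum() >= 2 and (vd == "NO_VD").sum() >= 2:
            problems.append(BinaryProblem(name="VD", X=X_all, y=vd, classes=("VD", "NO_VD")))
        else:
            warnings.warn("VD_PRESENCE: a class has <2 rows; skipped")
    elif scheme == "CONTROL_VS_MERGED":
        sel = table["vd_present"].to_numpy(dtype=bool)
        g_sel = groups[sel]
        y = np.where(g_sel == "CONTROL", "CONTROL", "MERGED")
        if (y == "CONTROL").sum() >= 2 and (y == "MERGED").sum() >= 2:
            problems.append(
                BinaryProblem(name="CONTROL-MERGED", X=X_all[sel], y=y,
                              classes=("CONTROL", "MERGED"))
            )
        else:
            warnings.warn("CONTROL_VS_MERGED: a class has <2 rows; skipped")
    else:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {', '.join(SCHEMES)}")
    return problems


def _evaluate(problem: BinaryProblem, cols: list[int], eval_method: str) -> float:
    Xs = problem.X[:, cols]
    if eval_method == "loocv":
        return loocv_accuracy(Xs, problem.y, problem.classes)
    model = fit_linear(Xs, problem.y, problem.classes)
    return accuracy(model, Xs, problem.y)


def subset_search(
    table: pd.DataFrame,
    scheme: str,
    feature_columns: Sequence[str] | None = None,
    eval_method: str = "resub",
) -> pd.DataFrame:
    """Evaluate every non-empty predictor subset under one scheme.

    Returns one row per (problem, subset) — for COMMON_PREDICTORS one row
    per subset with the accuracy averaged over the four one-vs-rest
    problems — sorted by (accuracy desc, n_predictors asc, bitmask asc).
    ``feature_columns`` restricts the searched predictors (e.g. means only).
    """
    if eval_method not in ("resub", "loocv"):
        raise ValueError("eval_method must be 'resub' or 'loocv'")
    feats = list(feature_columns if feature_columns is not None else PREDICTOR_COLUMNS)
    problems = _problems_for_scheme(table, scheme, feats)
    masks = enumerate_subsets(len(feats))
    rows = []
    if scheme == "COMMON_PREDICTORS":
        for mask in masks:
            cols = subset_indices(mask)
            accs = [_evaluate(pr, cols, eval_method) for pr in problems]
            rows.append(
                SearchResult(scheme, "common", mask, len(cols), float(np.mean(accs)))
            )
    else:
        for pr in problems:
            for mask in masks:
                cols = subset_indices(mask)
                rows.append(
                    SearchResult(scheme, pr.name, mask, len(cols), _evaluate(pr, cols, eval_method))
                )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df = df.sort_values(
            ["problem", "accuracy", "n_predictors", "bitmask"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df.attrs["feature_columns"] = feats
    return df


def best_subsets(results: pd.DataFrame) -> pd.DataFrame:
    """All subsets tied at (max accuracy, minimal size), per problem."""
    out = []
    for problem, sub in results.groupby("problem", sort=True):
        best_acc = sub["accuracy"].max()
        at_best = sub[np.isclose(sub["accuracy"], best_acc)]
        min_k = at_best["n_predictors"].min()
        out.append(at_best[at_best["n_predictors"] == min_k])
    return pd.concat(out, ignore_index=True) if out else results.iloc[0:0]


def pareto_front(results: pd.DataFrame) -> pd.DataFrame:
    """Non-dominated subsets under (maximize accuracy, minimize size).

    Expects results of a single problem; keeps, for each subset size on the
    front, the rows attaining the best accuracy among sizes <= that size,
    with accuracies strictly increasing along the front.
    """
    if len(results) == 0:
        raise ValueError("pareto_front requires nonempty results")
    front_rows = []
    best_so_far = -np.inf
    for k in sorted(results["n_predictors"].unique()):
        sub = results[results["n_predictors"] == k]
        acc_k = sub["accuracy"].max()
        if acc_k > best_so_far:
            front_rows.append(sub[np.isclose(sub["accuracy"], acc_k)])
            best_so_far = acc_k
    return pd.concat(front_rows, ignore_index=True)


def subset_flag_table(results: pd.DataFrame, feature_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Render results as an 'x'-grid over the ten predictors plus accuracy."""
    feats = list(feature_columns or results.attrs.get("feature_columns", PREDICTOR_COLUMNS))
    rows = []
    for _, r in results.iterrows():
        row = {"problem": r["problem"]}
        chosen = {feats[i] for i in subset_indices(int(r["bitmask"]))}
        for c in PREDICTOR_COLUMNS:
            row[c] = "x" if c in chosen else ("-" if c not in feats else "")
        row["n_predictors"] = int(r["n_predictors"])
        row["accuracy"] = r["accuracy"]
        rows.append(row)
    return pd.DataFrame(rows, columns=["problem"] + PREDICTOR_COLUMNS + ["n_predictors", "accuracy"])


def separation3d(
    table: pd.DataFrame,
    scheme: str,
    problem: str,
    predictors: Sequence[str],
    eval_method: str = "resub",
) -> tuple[pd.DataFrame, dict]:
    """Coordinates and separating plane for a chosen 3-predictor subset.

    Returns (points, plane) where points holds the three predictor columns
    plus the class label per row and plane holds the normal vector and
    offset of ``w . x + b = 0``.
    """
    predictors = list(predictors)
    if len(predictors) != 3:
        raise ValueError("separation3d expects exactly 3 predictors")
    problems = {p.name: p for p in _problems_for_scheme(table, scheme, predictors)}
    if problem not in problems:
        raise ValueError(f"unknown problem {problem!r} for scheme {scheme}")
    pr = problems[problem]
    model = fit_linear(pr.X, pr.y, pr.classes)
    points = pd.DataFrame(pr.X, columns=predictors)
    points["class"] = pr.y
    plane = {
        "predictors": predictors,
        "normal": model.weights.tolist(),
        "offset": model.intercept,
        "accuracy": accuracy(model, pr.X, pr.y),
    }
    return points, plane


def run_all_schemes(
    table: pd.DataFrame,
    schemes: Sequence[str] = SCHEMES,
    eval_method: str = "resub",
    feature_columns: Sequence[str] | None = None,
    subset_3d: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the exhaustive search for every scheme and assemble report tables.

    Returns a dict with, per scheme, ``best_subsets_<scheme>`` ('x'-grid of
    all tied best subsets) and ``pareto_<scheme>``; plus
    ``common_histogram`` (the 1023 COMMON_PREDICTORS average accuracies)
    and, if ``subset_3d`` names three predictors, ``separation3d`` data for
    the PAIRED problems.
    """
    out: dict[str, pd.DataFrame] = {}
    for scheme in schemes:
        results = subset_search(table, scheme, feature_columns, eval_method)
        if len(results) == 0:
            continue
        feats = results.attrs["feature_columns"]
        out[f"results_{scheme.lower()}"] = results
        out[f"best_subsets_{scheme.lower()}"] = subset_flag_table(best_subsets(results), feats)
        fronts = []
        for problem, sub in results.groupby("problem", sort=True):
            f = pareto_front(sub)
            fronts.append(subset_flag_table(f, feats))
        out[f"pareto_{scheme.lower()}"] = pd.concat(fronts, ignore_index=True)
        if scheme == "COMMON_PREDICTORS":
            out["common_histogram"] = results[["bitmask", "n_predictors", "accuracy"]].copy()
    if subset_3d is not None:
        rows = []
        for problem in ("CONTROL-TMG", "CONTROL-CMG", "CONTROL-CEG"):
            try:
                points, plane = separation3d(table, "PAIRED", problem, subset_3d, eval_method)
            except ValueError:
                continue
            points = points.copy()
            points["problem"] = problem
            for i, c in enumerate(subset_3d):
                points[f"plane_w_{c}"] = plane["normal"][i]
            points["plane_offset"] = plane["offset"]
            rows.append(points)
        if rows:
            out["separation3d"] = pd.concat(rows, ignore_index=True)
    return out
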