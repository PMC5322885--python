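"""Per-label summary statistics and the comparison statistics used to judge
shape measures: fractional difference, distance correlation, and asymmetric
curve-to-curve distances.

Estimator conventions (recorded in table metadata): quartiles interpolate
linearly between order statistics, skewness/kurtosis are population moment
estimators (kurtosis is excess), and the MAD carries no normal-consistency
factor because it doubles as a raw threshold unit elsewhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.spatial import cKDTree

from .io_formats import LabelField, ScalarField, ShapeTable, TriangleMesh

logger = logging.getLogger(__name__)

STAT_COLUMNS = [
    "median",
    "mad",
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "lower_quartile",
    "upper_quartile",
]

UNDEFINED = np.nan


def summarize(values: np.ndarray) -> dict:
    """The eight summary statistics of one distribution of shape values."""
    v = np.asarray(values, dtype=np.float64)
    med = float(np.median(v))
    return {
        "median": med,
        "mad": float(np.median(np.abs(v - med))),
        "mean": float(np.mean(v)),
        "std": float(np.std(v)),
        "skewness": float(_sstats.skew(v)) if len(v) > 1 and np.ptp(v) > 0 else 0.0,
        "kurtosis": float(_sstats.kurtosis(v)) if len(v) > 1 and np.ptp(v) > 0 else 0.0,
        "lower_quartile": float(np.quantile(v, 0.25)),
        "upper_quartile": float(np.quantile(v, 0.75)),
    }


def stats_per_label(
    field: ScalarField,
    labels: LabelField,
    areas: ScalarField | None = None,
) -> ShapeTable:
    """One row of summary statistics per label >= 0 (background -1 excluded).

    When per-vertex areas are supplied, a surface_area column (their sum per
    label) is appended.
    """
    if len(field.values) != len(labels.labels):
        raise ValueError("field and labels must be aligned")
    if areas is not None and len(areas.values) != len(labels.labels):
        raise ValueError("areas must be aligned to the labels")
    rows = []
    for lab in np.unique(labels.labels):
        if lab < 0:
            continue
        sel = labels.labels == lab
        if not sel.any():
            continue
        row = {"region_id": int(lab), "measure": field.name}
        row.update(summarize(field.values[sel]))
        if areas is not None:
            row["surface_area"] = float(areas.values[sel].sum())
        rows.append(row)
    cols = ["region_id", "measure"] + STAT_COLUMNS + (
        ["surface_area"] if areas is not None else []
    )
    return ShapeTable(
        pd.DataFrame(rows, columns=cols),
        metadata={
            "quartiles": "linear interpolation (inclusive)",
            "moments": "population estimators; kurtosis is excess",
            "mad": "unscaled",
        },
    )


def fractional_difference(a: ShapeTable, b: ShapeTable) -> ShapeTable:
    """|a - b| / a per (region_id, measure) key and numeric column.

    Zero baseline values yield NaN with a warning (undefined fraction).
    Mismatched keys raise, listing the offenders.
    """
    keys = ["region_id"] + (["measure"] if "measure" in a.data.columns else [])
    da = a.sorted().set_index(keys)
    db = b.sorted().set_index(keys)
    missing = sorted(set(da.index.tolist()) ^ set(db.index.tolist()))
    if missing:
        raise ValueError(f"tables do not share keys; unmatched: {missing}")
    num = [c for c in da.columns if np.issubdtype(da[c].dtype, np.number)]
    da_n, db_n = da[num], db[num].reindex(da.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (da_n - db_n).abs() / da_n
    zero = (da_n == 0)
    if zero.any().any():
        logger.warning("%d zero baseline values; fractional difference undefined",
                       int(zero.sum().sum()))
        frac = frac.mask(zero, UNDEFINED)
    return ShapeTable(frac.reset_index(), metadata={"definition": "|a-b|/a"})


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation in [0, 1] (double-centered V-statistic form).

    1 exactly under affine dependence, 0 in the limit only for independent
    samples.  Constant inputs are rejected (the denominator vanishes).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must share a length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("distance correlation is undefined for constant input")

    def centered(v: np.ndarray) -> np.ndarray:
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    ax, ay = centered(x), centered(y)
    dcov2 = (ax * ay).mean()
    dvarx = (ax * ax).mean()
    dvary = (ay * ay).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def curve_to_curve_distance(
    a, b, mesh: TriangleMesh
) -> tuple[float, float, float, float]:
    """(mean_ab, mean_ba, max_ab, max_ba) of nearest-point Euclidean
    distances between two vertex sets, in mm.  Asymmetric by construction."""
    a = np.asarray(sorted(set(int(v) for v in a)), dtype=np.int64)
    b = np.asarray(sorted(set(int(v) for v in b)), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both vertex sets must be non-empty")
    pa, pb = mesh.coordinates[a], mesh.coordinates[b]
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return (
        float(d_ab.mean()),
        float(d_ba.mean()),
        float(d_ab.max()),
        float(d_ba.max()),
    )
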