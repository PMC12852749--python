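"""LOOCV of interpolated surfaces and correlation analysis.

Leave-one-out cross-validation quantifies how well the IDW surface would
have predicted each observation from the others: every sample point is
omitted in turn, re-estimated from the remaining points with the same
interpolation settings, and the paired (observed, predicted) errors are
summarized as

    RMSE = sqrt(mean((z_i - zhat_i)^2))      MAE = mean(|z_i - zhat_i|)

LOOCV operates over *points*, not sites: lateral-sector points at the
same site stay in the prediction pool when a co-located point is left
out.

Pearson product-moment correlations relate site-level water chemistry to
the computed indices: records are averaged per (site, sector, season)
group and parameter, the two index scores are appended as variables, and
the full symmetric r matrix is returned with t-transform p-values
(reported raw, without multiple-testing correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Dataset, StandardsRegistry
from .idw import IdwConfig, idw_batch, merge_duplicates, project_coords
from .indices import compute_indices

log = logging.getLogger(__name__)


@dataclass
class LoocvResult:
    """LOOCV error summary for one (parameter, season) surface."""

    parameter: str
    season: str
    observed: np.ndarray
    predicted: np.ndarray
    rmse: float
    mae: float
    n: int
    unit: str = ""


def rmse(observed, predicted) -> float:
    """Root mean square prediction error."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise ValueError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def mae(observed, predicted) -> float:
    """Mean absolute prediction error."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise ValueError("mae needs at least one pair")
    return float(np.mean(np.abs(observed - predicted)))


def loocv_predict(
    xy: np.ndarray, z: np.ndarray, cfg: IdwConfig = IdwConfig()
) -> np.ndarray:
    """Leave-one-out IDW predictions, in input order.

    Each value is re-estimated from all *other* points with the same
    configuration.  Coincident duplicates of the held-out point remain
    in the pool (they are distinct measurements), so predictions at
    duplicated coordinates equal the co-located values.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    z = np.asarray(z, dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("LOOCV needs at least two sample points")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        preds[i] = idw_batch(xy[i], xy[rest], z[rest], cfg)[0]
    return preds


def validation_report(
    dataset: Dataset,
    registry: StandardsRegistry,
    cfg: IdwConfig = IdwConfig(),
) -> list[LoocvResult]:
    """One LOOCV error summary per (parameter, season) with >= 2 points.

    Replicate measurements at one point are averaged before the
    cross-validation (the surface interpolates point means).  Parameters
    with fewer than two distinct points in a season are skipped with a
    warning.
    """
    frame = dataset.to_frame()
    results: list[LoocvResult] = []
    if frame.empty:
        return results
    grouped = frame.groupby(["parameter", "season"], sort=True)
    for (parameter, season), sub in grouped:
        pts = (
            sub.groupby(["longitude", "latitude"], sort=True)["value"]
            .mean()
            .reset_index()
        )
        if len(pts) < 2:
            log.warning(
                "WARN %s/%s has %d point(s); skipped from the LOOCV report",
                parameter,
                season,
                len(pts),
            )
            continue
        x, y = project_coords(pts["longitude"].to_numpy(), pts["latitude"].to_numpy())
        xy = np.column_stack([x, y])
        z = pts["value"].to_numpy()
        xy, z = merge_duplicates(xy, z)
        pred = loocv_predict(xy, z, cfg)
        pdef = registry.get(parameter)
        results.append(
            LoocvResult(
                parameter=parameter,
                season=season,
                observed=z,
                predicted=pred,
                rmse=rmse(z, pred),
                mae=mae(z, pred),
                n=len(z),
                unit=pdef.unit if pdef is not None else "",
            )
        )
    return results


def validation_table(results: list[LoocvResult]):
    """LOOCV report as a DataFrame (parameter, season, RMSE, MAE, n, unit)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "season": r.season,
                "rmse": r.rmse,
                "mae": r.mae,
                "n": r.n,
                "unit": r.unit,
            }
            for r in results
        ]
    )


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix with p-values and pair counts."""

    labels: list[str]
    r: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)

    def p_frame(self):
        import pandas as pd

        return pd.DataFrame(self.p, index=self.labels, columns=self.labels)


def pearson_matrix(
    dataset: Dataset,
    registry: StandardsRegistry,
    include_indices: bool = True,
    pool_seasons: bool = False,
    include_nonstatutory_in_indices: bool = False,
) -> CorrelationMatrix:
    """Pearson correlations across parameters (and index scores).

    Records are aggregated to one row per (site, sector, season) group
    (or per (site, sector) with seasons pooled) by averaging each
    parameter; WAWQI and CWQI scores computed on the same grouping are
    appended when ``include_indices``.  Variables with zero variance are
    flagged and their correlations reported as NaN.
    """
    frame = dataset.to_frame()
    keys = ["site_id", "sector"] if pool_seasons else ["site_id", "sector", "season"]
    wide = (
        frame.groupby(keys + ["parameter"], sort=True)["value"]
        .mean()
        .unstack("parameter")
    )
    if include_indices:
        idx = compute_indices(
            dataset,
            registry,
            pool_seasons=pool_seasons,
            include_nonstatutory=include_nonstatutory_in_indices,
        ).set_index(keys if pool_seasons else ["site_id", "sector", "season"])
        wide = wide.join(idx[["wawqi", "cwqi"]].rename(
            columns={"wawqi": "WAWQI", "cwqi": "CWQI"}
        ))
    wide = wide.dropna(axis=0, how="any")
    if len(wide) < 3:
        raise ValueError(
            f"pearson_matrix needs >= 3 complete groups, got {len(wide)}"
        )
    labels = list(wide.columns)
    data = wide.to_numpy(dtype=float)
    n_groups, n_vars = data.shape
    r = np.full((n_vars, n_vars), np.nan)
    p = np.full((n_vars, n_vars), np.nan)
    n_pairs = np.full((n_vars, n_vars), n_groups, dtype=int)
    sd = data.std(axis=0)
    for a in range(n_vars):
        if sd[a] == 0:
            log.warning("WARN variable %s has zero variance; r undefined", labels[a])
            continue
        r[a, a] = 1.0
        p[a, a] = 0.0
        for b in range(a + 1, n_vars):
            if sd[b] == 0:
                continue
            res = stats.pearsonr(data[:, a], data[:, b])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    return CorrelationMatrix(labels=labels, r=r, p=p, n_pairs=n_pairs)
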