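"""Mahalanobis D2 habitat-suitability modelling and Boyce-index evaluation.

The niche model is the mean vector and covariance matrix of the EGVs at the
(thinned, settled-period) used locations, pooled over animals.  For each
resource unit the squared Mahalanobis distance

    D2 = (x - mu)^T Sigma^{-1} (x - mu)

measures dissimilarity from the typical used conditions; under multivariate
normality D2 follows a chi-square distribution with p degrees of freedom
(p = number of EGVs), so the chi-square survival function maps D2 to a
suitability p-value in [0, 1] (1 at the niche centre, decreasing with D2).

Evaluation uses the predicted-to-expected ratio F_i = P_i / E_i across 20
fixed suitability classes of width 0.05: P_i is the fraction of evaluation
points in class i, E_i the fraction of valid area.  F_i = 1 marks random use;
the first upcrossing of 1 that stays above 1 gives the threshold for
reclassifying the map into unsuitable (F < 1) and suitable (F > 1) habitat.
The Boyce index is the Spearman rank correlation between F_i and class rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .resource_units import RasterGrid, RUStack

logger = logging.getLogger("habselect")


@dataclass
class NicheModel:
    mean: np.ndarray
    cov: np.ndarray
    columns: list[str]
    n: int
    condition_number: float

    @property
    def p(self) -> int:
        return len(self.mean)


def select_niche_columns(
    used_values: pd.DataFrame,
    cover_classes: list[int] | None = None,
) -> list[str]:
    """Choose EGV columns that give a non-degenerate covariance.

    Cover-class proportions sum to 1 per RU, so using the full set makes the
    covariance exactly singular; worse, when a class is absent from the used
    locations the remaining proportions still sum to a constant.  Dropping
    the proportion column with the *largest* variance at the used locations
    leaves a complement that actually varies.  Columns constant at the used
    locations are dropped too (they carry no niche information and break the
    fit).
    """
    cols = [c for c in used_values.columns
            if c not in ("ru_id", "x", "y", "zone")]
    var = used_values[cols].var(ddof=1)
    cols = [c for c in cols if var[c] > 1e-12]
    prop_cols = [c for c in cols if c.startswith("prop_")]
    if prop_cols:
        drop = max(prop_cols, key=lambda c: var[c])
        cols.remove(drop)
    return cols


def fit_niche(
    used_values: pd.DataFrame,
    columns: list[str] | None = None,
    ridge: float = 0.0,
    max_condition: float = 1e8,
) -> NicheModel:
    """Fit the multivariate-normal niche model on used-location EGVs.

    EGVs stay on their original scales (the Mahalanobis form is
    scale-equivariant).  Conditioning is assessed on the *correlation*
    matrix — the covariance mixes units (metres^2, degrees^2, proportions)
    so its raw condition number is dominated by scale, which Mahalanobis
    distance is invariant to.  A near-singular correlation structure
    (condition number above ``max_condition``) raises unless a ridge epsilon
    is given, in which case ridge * diag(cov) is added (and logged).
    """
    if columns is None:
        columns = [c for c in used_values.columns
                   if c not in ("ru_id", "x", "y", "zone")]
    X = used_values[columns].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more locations ({n}) than EGVs ({p})")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if ridge > 0:
        logger.info("applying ridge regularization epsilon=%g", ridge)
        cov = cov + ridge * np.diag(np.diag(cov))
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ValueError("an EGV is constant at the used locations; drop it "
                         "(see select_niche_columns)")
    corr = cov / np.outer(sd, sd)
    cond = float(np.linalg.cond(corr))
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"EGV correlation matrix is near-singular (condition number "
            f"{cond:.3g}); drop redundant columns or supply a ridge epsilon"
        )
    return NicheModel(mu, cov, list(columns), n, cond)


def mahalanobis_d2(X: np.ndarray, model: NicheModel) -> np.ndarray:
    """Squared Mahalanobis distances of rows of X from the niche centre."""
    diff = np.atleast_2d(X) - model.mean
    sol = np.linalg.solve(model.cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def suitability_map(
    stack: RUStack, model: NicheModel
) -> tuple[RasterGrid, RasterGrid]:
    """D2 and chi-square p-value suitability rasters at RU scale.

    Suitability = sf(D2; chi2 with p df): 1 where the RU matches the niche
    centre, monotonically decreasing in D2.  Nodata propagates.
    """
    any_grid = next(iter(stack.grids.values()))
    table = stack.table
    X = table[model.columns].to_numpy(dtype=float)
    d2 = mahalanobis_d2(X, model)
    pvals = stats.chi2.sf(d2, df=model.p)

    shape = any_grid.values.shape
    nodata = any_grid.nodata
    d2_vals = np.full(shape, nodata)
    p_vals = np.full(shape, nodata)
    rows = (table["ru_id"] // any_grid.n_cols).to_numpy()
    cols = (table["ru_id"] % any_grid.n_cols).to_numpy()
    d2_vals[rows, cols] = d2
    p_vals[rows, cols] = pvals
    geom = (any_grid.cell_size, any_grid.origin, nodata)
    return RasterGrid(d2_vals, *geom), RasterGrid(p_vals, *geom)


@dataclass
class FiCurve:
    table: pd.DataFrame        # class_index, lo, hi, P, E, F (E>0 classes)
    n_classes: int
    threshold: float | None    # suitability value; None when no upcrossing
    boyce_r: float | None = None
    adjusted_r2: float | None = None


def fi_curve(
    suitability: RasterGrid,
    eval_points: np.ndarray,
    n_classes: int = 20,
    threshold_rule: str = "first_upcrossing",
) -> FiCurve:
    """Predicted-to-expected frequency curve over fixed suitability classes.

    Classes are [i/n, (i+1)/n) with the top class closed at 1.  Classes with
    zero area (E_i = 0) are excluded.  The reclassification threshold is the
    lower bound of the first class (scanning upward) from which F stays above
    1 ("first_upcrossing"); "last_upcrossing" takes the last crossing instead.
    """
    vals = suitability.values
    valid = suitability.valid_mask()
    if not valid.any():
        raise ValueError("suitability raster has no valid cells")
    edges = np.linspace(0.0, 1.0, n_classes + 1)

    area_counts, _ = np.histogram(vals[valid], bins=edges)
    E = area_counts / area_counts.sum()

    pts = np.asarray(eval_points, dtype=float)
    sv = []
    for x, y in pts:
        r, c = suitability.point_to_cell(x, y)
        if not valid[r, c]:
            continue
        sv.append(vals[r, c])
    if not sv:
        raise ValueError("all evaluation points fall on nodata cells")
    pt_counts, _ = np.histogram(np.asarray(sv), bins=edges)
    P = pt_counts / pt_counts.sum()

    nonempty = E > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(nonempty, P / np.where(nonempty, E, 1.0), np.nan)
    tab = pd.DataFrame({
        "class_index": np.arange(1, n_classes + 1),
        "lo": edges[:-1],
        "hi": edges[1:],
        "P": P,
        "E": E,
        "F": F,
    })[nonempty].reset_index(drop=True)

    # renormalize over the retained (non-empty) classes
    tab["P"] = tab["P"] / tab["P"].sum() if tab["P"].sum() > 0 else tab["P"]
    tab["E"] = tab["E"] / tab["E"].sum()
    tab["F"] = tab["P"] / tab["E"]

    above = (tab["F"] > 1).to_numpy()
    threshold = None
    if above.any():
        if threshold_rule == "first_upcrossing":
            # first class from which F stays above 1 through the top class
            suffix_all = np.logical_and.accumulate(above[::-1])[::-1]
            if suffix_all.any():
                threshold = float(tab["lo"].iloc[int(np.argmax(suffix_all))])
        elif threshold_rule == "last_upcrossing":
            # first index of the final run of F > 1
            runs = np.nonzero(above & ~np.r_[False, above[:-1]])[0]
            threshold = float(tab["lo"].iloc[runs[-1]])
        else:
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return FiCurve(tab, n_classes, threshold)


def boyce_index(curve: FiCurve) -> FiCurve:
    """Spearman correlation of F_i with class rank, plus adjusted r^2.

    Requires >= 3 non-empty classes.  Constant F has zero variance: the curve
    is returned with boyce_r = None and a warning logged.
    """
    tab = curve.table
    if len(tab) < 3:
        raise ValueError("need at least 3 non-empty suitability classes")
    F = tab["F"].to_numpy()
    ranks = tab["class_index"].to_numpy(dtype=float)
    if np.allclose(F, F[0]):
        logger.warning("F is constant across classes: Boyce index undefined")
        curve.boyce_r = None
        curve.adjusted_r2 = None
        return curve
    rho, _ = stats.spearmanr(ranks, F)
    lin = stats.linregress(ranks, F)
    n = len(F)
    r2 = lin.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    curve.boyce_r = float(rho)
    curve.adjusted_r2 = float(adj)
    return curve


def reclassify_and_summarize(
    suitability: RasterGrid,
    curve: FiCurve,
    zones: RasterGrid | None = None,
) -> tuple[RasterGrid, pd.DataFrame]:
    """Binary suitable/unsuitable raster and percent suitable per zone.

    A cell is suitable iff its suitability p-value >= the curve's threshold.
    Without a zone raster a single "all" zone is summarized.
    """
    if curve.threshold is None:
        raise ValueError("Fi curve has no defined threshold")
    valid = suitability.valid_mask()
    suit = (suitability.values >= curve.threshold) & valid
    binary = np.where(valid, suit.astype(float), suitability.nodata)
    out = RasterGrid(binary, suitability.cell_size, suitability.origin,
                     suitability.nodata)
    rows = []
    if zones is None:
        n_valid = int(valid.sum())
        rows.append(dict(zone="all", n_cells=n_valid,
                         n_suitable=int(suit.sum()),
                         percent_suitable=100.0 * suit.sum() / n_valid))
    else:
        if not zones.same_geometry(suitability):
            raise ValueError("zone raster is not co-registered")
        zvalid = zones.valid_mask() & valid
        if not zvalid.any():
            raise ValueError("no overlap between zones and valid suitability")
        for z in np.unique(zones.values[zvalid]):
            mask = zvalid & (zones.values == z)
            n = int(mask.sum())
            ns = int((suit & mask).sum())
            rows.append(dict(zone=z, n_cells=n, n_suitable=ns,
                             percent_suitable=100.0 * ns / n))
    return out, pd.DataFrame(rows)
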