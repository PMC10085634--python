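"""Replicate- and condition-level quality control for colony screens.

Four tests target the errors that commonly corrupt large arrayed screens —
unequal pinning, mislabelled plates, inverted images and failed colony
detection:

* **Z-score percentage normality** (per replicate plate): each position's
  replicate values are standardized; a colony is abnormal if missing or
  ``|Z| > 1``, and the plate's score is the percentage of normal colonies.
* **Mann-Whitney replicate concordance** (per replicate plate): each
  replicate's colony-size distribution is compared against every other
  replicate of the same condition; the plate's score is its mean p-value.
* **Condition-level variance tests**: the variance of the replicates'
  Mann-Whitney mean p-values, and the mean across positions of the
  across-replicate colony variance.

Thresholds are the user's choice; ``threshold_curves`` tabulates how much
data each candidate threshold would discard, and ``curate`` applies chosen
thresholds and re-normalizes the surviving data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import normalization
from .iris_io import FLAG_QC_REMOVED, ScreenDataset

logger = logging.getLogger(__name__)

#: Normality threshold grid printed in the percentage-normality loss curves.
DEFAULT_NORMALITY_GRID = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
#: Number of quantile-derived thresholds for the statistic-range-based grids.
DEFAULT_N_QUANTILE_THRESHOLDS = 7


def _replicate_zscores(block: np.ndarray) -> np.ndarray:
    """Standardize each row (position) of a positions x replicates array
    across its replicates, using the sample (n-1) standard deviation.
    A zero-spread row gets Z = 0 everywhere: constant replicates are
    maximally concordant, not outliers."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(block, axis=1, keepdims=True)
        std = np.nanstd(block, axis=1, keepdims=True, ddof=1)
    z = np.where(np.isfinite(block), block - mean, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.divide(z, std, out=z, where=std != 0)
    # zero or undefined spread (constant replicates, or a lone observation):
    # the value carries no evidence of being an outlier
    degenerate = np.broadcast_to(~np.isfinite(std) | (std == 0), z.shape)
    z[degenerate & np.isfinite(block)] = 0.0
    return z


def zscore_normality(ds: ScreenDataset, condition: str) -> dict[str, float]:
    """Percentage normality of each replicate plate of a condition.

    Per position, replicate values are Z-scored against the across-replicate
    mean and sample std; a cell is abnormal if missing or ``|Z| > 1``
    (strict).  Returns ``{replicate: percentage in [0, 100]}``.
    """
    block = ds.condition_block(condition)
    if block.shape[1] < 2:
        raise ValueError(
            f"condition {condition!r} has {block.shape[1]} replicate(s); "
            "the Z-score test needs at least 2")
    if block.shape[1] == 2:
        logger.warning("condition %r has exactly 2 replicates: |Z| is always "
                       "1/sqrt(2) < 1, so the Z-score test cannot flag "
                       "outliers, only missing values", condition)
    z = _replicate_zscores(block.to_numpy(dtype=float))
    abnormal = ~np.isfinite(z) | (np.abs(z) > 1)
    pct = 100.0 * (1.0 - abnormal.mean(axis=0))
    return {rep: float(p) for rep, p in zip(block.columns, pct)}


def mannwhitney_replicates(ds: ScreenDataset, condition: str,
                           min_n: int = 3) -> dict[str, float]:
    """Mean pairwise Mann-Whitney p-value per replicate plate.

    Every unordered replicate pair is compared with a two-sided Mann-Whitney
    test on non-missing colony sizes; each replicate's score averages the
    p-values of the pairs that include it.  Pairs where either side has
    fewer than ``min_n`` values are skipped and logged.
    """
    block = ds.condition_block(condition)
    reps = list(block.columns)
    if len(reps) < 2:
        raise ValueError(f"condition {condition!r} needs >= 2 replicates")
    pvals: dict[str, list[float]] = {r: [] for r in reps}
    for a, b in itertools.combinations(reps, 2):
        x = block[a].dropna().to_numpy()
        y = block[b].dropna().to_numpy()
        if x.size < min_n or y.size < min_n:
            logger.warning("condition %r: pair (%s, %s) skipped "
                           "(insufficient data)", condition, a, b)
            continue
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        pvals[a].append(p)
        pvals[b].append(p)
    return {r: (float(np.mean(ps)) if ps else float("nan"))
            for r, ps in pvals.items()}


def condition_level_stats(
    ds: ScreenDataset, condition: str,
    mw_scores: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Condition-level reproducibility statistics.

    Returns ``(mw_p_variance, mean_colony_variance)``: the variance of the
    replicates' Mann-Whitney mean p-values, and the mean over positions
    (with >= 2 non-missing replicates) of the across-replicate sample
    variance.  Both are large when a whole condition is unreliable.
    """
    if mw_scores is None:
        mw_scores = mannwhitney_replicates(ds, condition)
    ps = np.array([v for v in mw_scores.values() if np.isfinite(v)])
    mw_p_variance = float(np.var(ps, ddof=1)) if ps.size >= 2 else float("nan")

    block = ds.condition_block(condition).to_numpy(dtype=float)
    n = np.isfinite(block).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(block, axis=1, ddof=1)
    var = var[n >= 2]
    mean_colony_variance = float(np.mean(var)) if var.size else float("nan")
    return mw_p_variance, mean_colony_variance


@dataclass
class QCReport:
    """Per-plate and per-condition quality statistics."""
    plate_stats: pd.DataFrame      # index (condition, replicate)
    condition_stats: pd.DataFrame  # index condition

    def to_tsv(self, plate_path, condition_path) -> None:
        self.plate_stats.reset_index().to_csv(plate_path, sep="\t", index=False)
        self.condition_stats.reset_index().to_csv(condition_path, sep="\t",
                                                  index=False)


def qc_report(ds: ScreenDataset) -> QCReport:
    """Run the full QC battery over every condition of a dataset."""
    plate_rows = []
    cond_rows = []
    for condition in ds.conditions:
        norm = zscore_normality(ds, condition)
        mw = mannwhitney_replicates(ds, condition)
        mw_var, colony_var = condition_level_stats(ds, condition, mw_scores=mw)
        for rep in ds.replicates(condition):
            plate_rows.append({
                "condition": condition, "replicate": rep,
                "pct_normality": norm[rep], "mw_mean_p": mw[rep],
            })
        cond_rows.append({
            "condition": condition,
            "mw_p_variance": mw_var,
            "mean_colony_variance": colony_var,
        })
    plate_stats = pd.DataFrame.from_records(plate_rows).set_index(
        ["condition", "replicate"])
    condition_stats = pd.DataFrame.from_records(cond_rows).set_index("condition")
    return QCReport(plate_stats=plate_stats, condition_stats=condition_stats)


def _quantile_grid(values: np.ndarray,
                   k: int = DEFAULT_N_QUANTILE_THRESHOLDS) -> np.ndarray:
    """Thresholds spanning the observed range of a statistic (k quantiles)."""
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.array([])
    return np.quantile(values, np.linspace(0, 1, k + 2)[1:-1])


def threshold_curves(
    report: QCReport,
    normality_grid=DEFAULT_NORMALITY_GRID,
    mw_grid=None,
    mw_var_grid=None,
    colony_var_grid=None,
) -> dict[str, pd.DataFrame]:
    """Data-loss tables over candidate thresholds for each QC test.

    For the plate-level tests (normality and Mann-Whitney, which fail LOW)
    the table gives, per condition, the percentage of replicate plates lost
    at each threshold.  For the condition-level variance tests (fail HIGH)
    it gives the total number of conditions lost.  Grids not supplied
    default to quantiles of the observed statistic range (normality keeps
    its conventional 20-80% grid).
    """
    if report.plate_stats.empty:
        raise ValueError("empty QC report")
    ps = report.plate_stats
    cs = report.condition_stats
    out: dict[str, pd.DataFrame] = {}

    def plate_loss(col: str, grid) -> pd.DataFrame:
        rows = []
        for condition, grp in ps.groupby(level="condition", sort=False):
            stat = grp[col].to_numpy()
            for t in grid:
                rows.append({"condition": condition, "threshold": float(t),
                             "pct_plates_lost":
                                 100.0 * float(np.mean(stat < t))})
        return pd.DataFrame.from_records(rows)

    def condition_loss(col: str, grid) -> pd.DataFrame:
        stat = cs[col].to_numpy()
        return pd.DataFrame.from_records(
            [{"threshold": float(t),
              "n_conditions_lost": int(np.sum(stat > t))} for t in grid])

    out["pct_normality"] = plate_loss("pct_normality",
                                      np.asarray(normality_grid))
    if mw_grid is None:
        mw_grid = _quantile_grid(ps["mw_mean_p"].to_numpy())
    out["mw_mean_p"] = plate_loss("mw_mean_p", np.asarray(mw_grid))
    if mw_var_grid is None:
        mw_var_grid = _quantile_grid(cs["mw_p_variance"].to_numpy())
    out["mw_p_variance"] = condition_loss("mw_p_variance",
                                          np.asarray(mw_var_grid))
    if colony_var_grid is None:
        colony_var_grid = _quantile_grid(cs["mean_colony_variance"].to_numpy())
    out["mean_colony_variance"] = condition_loss("mean_colony_variance",
                                                 np.asarray(colony_var_grid))
    return out


@dataclass
class QCThresholds:
    """User-chosen cut-offs; ``None`` disables a test.

    Plate-level tests fail LOW (plate removed when statistic < threshold);
    condition-level variance tests fail HIGH (condition removed when
    statistic > threshold).
    """
    normality: float | None = None
    mw_plate: float | None = None
    mw_variance: float | None = None
    colony_variance: float | None = None


@dataclass
class CurationResult:
    dataset: ScreenDataset
    removed_plates: pd.DataFrame
    removed_conditions: pd.DataFrame
    report: normalization.NormalizationReport | None = None


def curate(
    ds: ScreenDataset,
    report: QCReport,
    thresholds: QCThresholds,
    renormalize: bool = True,
    alpha: float = normalization.DEFAULT_ALPHA,
) -> CurationResult:
    """Remove failing replicate plates and conditions, then re-normalize.

    A replicate plate is removed when it fails *either* enabled plate-level
    test; a condition is removed when it fails either enabled
    condition-level test.  Every removal is logged with the failing
    statistic.  With no thresholds supplied the dataset is returned
    unchanged.
    """
    ps = report.plate_stats
    cs = report.condition_stats

    plate_fail = pd.Series(False, index=ps.index)
    reason = pd.Series("", index=ps.index, dtype=object)
    if thresholds.normality is not None:
        bad = ps["pct_normality"] < thresholds.normality
        reason[bad & ~plate_fail] = "pct_normality"
        plate_fail |= bad
    if thresholds.mw_plate is not None:
        bad = ps["mw_mean_p"] < thresholds.mw_plate
        reason[bad & ~plate_fail] = "mw_mean_p"
        plate_fail |= bad

    cond_fail = pd.Series(False, index=cs.index)
    cond_reason = pd.Series("", index=cs.index, dtype=object)
    if thresholds.mw_variance is not None:
        bad = cs["mw_p_variance"] > thresholds.mw_variance
        cond_reason[bad & ~cond_fail] = "mw_p_variance"
        cond_fail |= bad
    if thresholds.colony_variance is not None:
        bad = cs["mean_colony_variance"] > thresholds.colony_variance
        cond_reason[bad & ~cond_fail] = "mean_colony_variance"
        cond_fail |= bad

    removed_plates = ps[plate_fail].copy()
    removed_plates["reason"] = reason[plate_fail]
    removed_conditions = cs[cond_fail].copy()
    removed_conditions["reason"] = cond_reason[cond_fail]

    drop_cols = [key for key in ds.values.columns
                 if key[0] in set(removed_conditions.index)
                 or (plate_fail.get(key, False))]
    for key in drop_cols:
        why = (cond_reason.get(key[0]) or reason.get(key, "")) or "condition"
        logger.info("curation removed plate %s (failing %s)", key, why)

    kept = ds.values.columns.difference(drop_cols, sort=False)
    if len(kept) == 0:
        raise ValueError("chosen thresholds would remove every plate; "
                         "nothing written")
    out = ScreenDataset(
        values=ds.values.loc[:, kept].copy(),
        n_rows=ds.n_rows, n_cols=ds.n_cols,
        provenance=ds.provenance.loc[:, kept].copy(),
        measurement=ds.measurement,
    )
    norm_report = None
    if renormalize and drop_cols:
        out, norm_report = normalization.normalize_dataset(out, alpha=alpha)
    return CurationResult(dataset=out, removed_plates=removed_plates,
                          removed_conditions=removed_conditions,
                          report=norm_report)
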