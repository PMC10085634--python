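"""S-score fitness statistic, IQR scaling, significance calls and
clustered-matrix export.

The S-score is a modified t-statistic comparing a mutant's replicate colony
sizes in one condition against that same mutant's median size across *all*
conditions — the mutant serves as its own "simulated wildtype", so strains
with globally high or low growth are judged against their own baseline:

    S = (mu_exp - mu_cont) / sqrt(s_exp^2 / n_exp + s_cont^2 / n_cont)

where ``mu_exp``/``s_exp``/``n_exp`` summarize the replicates in the scored
condition (with ``s_exp`` bounded below by a per-plate relative variance
floor so that accidentally tight replicates cannot inflate the score) and
``mu_cont``/``s_cont``/``n_cont`` describe the cross-condition control.
Positive scores mean a fitness gain in that condition, negative a defect.

Scores in each scaling group (by default each condition x library-plate) are
then rescaled to an interquartile range of 1.35.  Because most mutants are
unaffected in most conditions, S-scores concentrate around zero; at IQR 1.35
the conventional outlier fence (1.5 x IQR beyond the quartiles) sits near
+/-2, and hits are called at S > 2 (gain) and S < -3 (loss; the stricter
negative cut compensates for loss-of-function phenotypes being far more
common).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .iris_io import ScreenDataset

logger = logging.getLogger(__name__)

#: Target interquartile range after per-group scaling.
IQR_TARGET = 1.35
#: Significance cut-offs (strict inequalities).
NEGATIVE_CUT = -3.0
POSITIVE_CUT = 2.0

CALL_NEGATIVE = "negative-hit"
CALL_NONE = "none"
CALL_POSITIVE = "positive-hit"

SCALE_BY_PLATE = "plate"       # per (condition, library_plate) group
SCALE_BY_CONDITION = "condition"


@dataclass
class SScoreMatrix:
    """Strain-position x condition matrix of S-scores.

    ``scores`` rows keep the full ``(plate, row, column, gene)`` index so
    scaling groups can be formed per library plate; ``calls`` mirrors
    ``scores`` after :func:`call_significance`.  ``intermediates`` holds the
    per-cell mu/s/n terms when requested.
    """

    scores: pd.DataFrame
    scaled: bool = False
    scaling_group: str = SCALE_BY_PLATE
    calls: pd.DataFrame | None = None
    intermediates: dict[str, pd.DataFrame] = field(default_factory=dict)

    def copy(self) -> "SScoreMatrix":
        return SScoreMatrix(
            scores=self.scores.copy(), scaled=self.scaled,
            scaling_group=self.scaling_group,
            calls=None if self.calls is None else self.calls.copy(),
            intermediates={k: v.copy() for k, v in self.intermediates.items()},
        )

    def by_gene(self) -> pd.DataFrame:
        """Scores indexed by gene only (positions collapse; genes pinned at
        several positions keep one row per position, suffixed)."""
        out = self.scores.copy()
        out.index = out.index.get_level_values("gene")
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.by_gene().reset_index().to_csv(path, sep="\t", index=False)


def sscore_cell(replicates, control_median: float,
                control_params: tuple[float, float],
                variance_floor: float) -> float:
    """S-score of a single (strain, condition) cell.

    ``control_params`` is ``(s_cont, n_cont)``.  The experimental std is the
    population std of the replicates, bounded below by ``variance_floor``; a
    single replicate uses the floor outright.  Non-finite results (zero
    denominator) become NaN — an infinite score carries no usable magnitude.
    """
    x = np.asarray(replicates, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    s_cont, n_cont = control_params
    mu_exp = float(x.mean())
    # population (ddof=0) std across replicates, floored from below
    s_exp = float(x.std(ddof=0)) if x.size >= 2 else 0.0
    s_exp = max(s_exp, variance_floor)
    denom = np.sqrt(s_exp ** 2 / x.size + s_cont ** 2 / n_cont)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (mu_exp - control_median) / denom
    return float(s) if np.isfinite(s) else float("nan")


def _cell_summaries(ds: ScreenDataset):
    """Per-cell replicate summaries: (mu_exp, s_exp_raw, n_exp) arrays of
    shape (positions, conditions)."""
    conditions = ds.conditions
    n_pos = ds.values.shape[0]
    mu = np.full((n_pos, len(conditions)), np.nan)
    sd = np.full_like(mu, np.nan)
    n = np.zeros_like(mu)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, condition in enumerate(conditions):
            block = ds.condition_block(condition).to_numpy(dtype=float)
            n[:, j] = np.isfinite(block).sum(axis=1)
            mu[:, j] = np.nanmean(block, axis=1)
            sd[:, j] = np.nanstd(block, axis=1, ddof=0)
    return conditions, mu, sd, n


def variance_floors(ds: ScreenDataset) -> pd.DataFrame:
    """Relative lower bound for the experimental std, per (condition,
    library plate).

    The floor is the median of the replicate *relative* stds (std / mean)
    across the strains of the same condition x library-plate group; a
    cell's std is bounded below by ``floor * mu_exp``.  Flooring in
    relative terms stops near-zero replicate spread from producing runaway
    scores while keeping the statistic equivariant under a uniform
    rescaling of any one strain — a strain that is simply 2x larger must
    not score systematically larger |S| than its peers.
    """
    conditions, mu, sd, n = _cell_summaries(ds)
    plates = ds.values.index.get_level_values("plate").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = sd / mu
    rows = []
    for j, condition in enumerate(conditions):
        for plate in ds.library_plates:
            sel = (plates == plate) & (n[:, j] >= 2)
            vals = rel[sel, j]
            vals = vals[np.isfinite(vals)]
            rows.append({"condition": condition, "library_plate": plate,
                         "floor": float(np.median(vals)) if vals.size else 0.0})
    return pd.DataFrame.from_records(rows).set_index(
        ["condition", "library_plate"])


def control_parameters(ds: ScreenDataset, strain=None) -> pd.DataFrame:
    """Cross-condition "simulated wildtype" parameters per strain position.

    ``mu_cont`` is the median of the position's non-missing values across
    every condition-replicate; ``n_cont`` the count contributing to it;
    ``s_cont = mu_cont * r`` where ``r`` is the dataset-median replicate
    relative error (median over cells of ``s_exp / mu_exp``), which keeps
    the control variance on the control's own scale.  Positions observed in
    fewer than 2 conditions get NaN parameters (their scores stay missing).
    """
    conditions, mu, sd, n = _cell_summaries(ds)
    arr = ds.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu_cont = np.nanmedian(arr, axis=1)
    n_cont = np.isfinite(arr).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        rel = sd / mu
    rel = rel[(n >= 2) & np.isfinite(rel)]
    rel_err = float(np.median(rel)) if rel.size else 0.0

    n_conditions_seen = (n >= 1).sum(axis=1)
    underobserved = n_conditions_seen < 2
    if underobserved.any():
        logger.warning("%d strain position(s) observed in < 2 conditions; "
                       "their S-scores will be missing",
                       int(underobserved.sum()))
    mu_cont = np.where(underobserved, np.nan, mu_cont)

    out = pd.DataFrame({
        "mu_cont": mu_cont,
        "s_cont": mu_cont * rel_err,
        "n_cont": n_cont,
    }, index=ds.values.index)
    out.attrs["median_relative_error"] = rel_err
    if strain is not None:
        return out[out.index.get_level_values("gene") == strain]
    return out


def sscore_matrix(ds: ScreenDataset,
                  keep_intermediates: bool = False) -> SScoreMatrix:
    """Compute the full (unscaled) S-score matrix of a normalized dataset."""
    conditions, mu, sd, n = _cell_summaries(ds)
    controls = control_parameters(ds)
    floors = variance_floors(ds)
    plates = ds.values.index.get_level_values("plate").to_numpy()

    rel_floor = np.zeros_like(mu)
    for j, condition in enumerate(conditions):
        for plate in ds.library_plates:
            rel_floor[plates == plate, j] = floors.loc[(condition, plate),
                                                       "floor"]
    floor_arr = rel_floor * np.where(np.isfinite(mu), mu, 0.0)
    s_exp = np.where(n >= 2, sd, 0.0)
    s_exp = np.maximum(s_exp, floor_arr)

    mu_cont = controls["mu_cont"].to_numpy()[:, None]
    s_cont = controls["s_cont"].to_numpy()[:, None]
    n_cont = controls["n_cont"].to_numpy(dtype=float)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(s_exp ** 2 / np.where(n > 0, n, np.nan)
                        + s_cont ** 2 / np.where(n_cont > 0, n_cont, np.nan))
        scores = (mu - mu_cont) / denom
    scores[~np.isfinite(scores)] = np.nan  # infinities carry no magnitude

    frame = pd.DataFrame(scores, index=ds.values.index, columns=conditions)
    frame.columns.name = "condition"
    m = SScoreMatrix(scores=frame)
    if keep_intermediates:
        idx = ds.values.index
        m.intermediates = {
            "mu_exp": pd.DataFrame(mu, index=idx, columns=conditions),
            "s_exp": pd.DataFrame(s_exp, index=idx, columns=conditions),
            "n_exp": pd.DataFrame(n, index=idx, columns=conditions),
            "controls": controls,
            "low_confidence": pd.DataFrame(n == 1, index=idx,
                                           columns=conditions),
        }
    return m


def _iqr(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def scale_scores(m: SScoreMatrix,
                 grouping: str = SCALE_BY_PLATE) -> SScoreMatrix:
    """Rescale each scaling group of scores to IQR :data:`IQR_TARGET`.

    ``grouping`` is ``"plate"`` (each condition x library-plate group — one
    physical plate's scores) or ``"condition"`` (each condition column).
    Groups with zero IQR are left unscaled and flagged in the log.
    """
    if grouping not in (SCALE_BY_PLATE, SCALE_BY_CONDITION):
        raise ValueError(f"unknown scaling group {grouping!r}")
    out = m.copy()
    arr = out.scores.to_numpy(dtype=float)
    plates = out.scores.index.get_level_values("plate").to_numpy()
    for j, condition in enumerate(out.scores.columns):
        groups = ([plates == p for p in np.unique(plates)]
                  if grouping == SCALE_BY_PLATE
                  else [np.ones(arr.shape[0], dtype=bool)])
        for sel in groups:
            iqr = _iqr(arr[sel, j])
            if not np.isfinite(iqr) or iqr == 0:
                logger.warning("scaling group (%s) has zero/undefined IQR; "
                               "left unscaled", condition)
                continue
            arr[sel, j] *= IQR_TARGET / iqr
    out.scores.loc[:, :] = arr
    out.scaled = True
    out.scaling_group = grouping
    return out


def call_significance(m: SScoreMatrix) -> SScoreMatrix:
    """Assign hit calls at the asymmetric thresholds (strict inequalities).

    Scores below -3 are negative hits (fitness defects), above 2 positive
    hits; scores at exactly a threshold are not called.
    """
    if not m.scaled:
        logger.warning("calling significance on unscaled scores; the -3/+2 "
                       "cut-offs assume IQR-1.35 scaling")
    out = m.copy()
    arr = out.scores.to_numpy(dtype=float)
    calls = np.full(arr.shape, CALL_NONE, dtype=object)
    calls[arr < NEGATIVE_CUT] = CALL_NEGATIVE
    calls[arr > POSITIVE_CUT] = CALL_POSITIVE
    calls[~np.isfinite(arr)] = CALL_NONE
    out.calls = pd.DataFrame(calls, index=out.scores.index,
                             columns=out.scores.columns)
    counts = pd.Series(calls.ravel()).value_counts()
    logger.info("significance calls: %s", counts.to_dict())
    return out


# ---------------------------------------------------------------------------
# hierarchical clustering and Java TreeView export

def uncentred_correlation_distance(data: np.ndarray) -> np.ndarray:
    """Pairwise-complete uncentred-Pearson distance matrix over rows.

    The uncentred correlation is the cosine similarity
    ``sum(xy) / sqrt(sum(x^2) sum(y^2))`` over the positions where both rows
    are observed; distance is 1 minus it (range [0, 2]).  Pairs with no
    overlap or a zero norm get the maximal distance 2.
    """
    n = data.shape[0]
    dist = np.zeros((n, n))
    finite = np.isfinite(data)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            if not both.any():
                dist[i, j] = dist[j, i] = 2.0
                continue
            x, y = data[i, both], data[j, both]
            denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
            if denom == 0:
                dist[i, j] = dist[j, i] = 2.0
                continue
            d = 1.0 - float((x * y).sum() / denom)
            dist[i, j] = dist[j, i] = d
    return dist


def _average_linkage(dist: np.ndarray) -> np.ndarray:
    condensed = dist[np.triu_indices_from(dist, k=1)]
    return hierarchy.linkage(condensed, method="average")


def _write_tree(path: Path, linkage: np.ndarray, prefix: str,
                node_prefix: str) -> list[str]:
    """Write a GTR/ATR tree file; returns leaf ids in dendrogram order."""
    n = linkage.shape[0] + 1
    names = [f"{prefix}{i}X" for i in range(n)]
    node_names = {}
    lines = []
    for k, (a, b, dist, _cnt) in enumerate(linkage):
        a, b = int(a), int(b)
        na = names[a] if a < n else node_names[a]
        nb = names[b] if b < n else node_names[b]
        node = f"{node_prefix}{k}X"
        node_names[n + k] = node
        lines.append(f"{node}\t{na}\t{nb}\t{1.0 - dist:.6f}")
    path.write_text("\n".join(lines) + "\n")
    order = hierarchy.leaves_list(linkage)
    return [names[i] for i in order]


def cluster_export(m: SScoreMatrix, out_prefix: str | Path) -> dict[str, Path]:
    """Hierarchically cluster rows and columns and write Java TreeView files.

    Rows (strains) and columns (conditions) are clustered with uncentred
    Pearson correlation distance (pairwise-complete) and average linkage;
    the output is the CDT/GTR/ATR triple TreeView-style viewers consume.
    Rows or columns with no finite score are dropped with a warning.
    """
    out_prefix = Path(out_prefix)
    scores = m.by_gene()
    keep_rows = np.isfinite(scores.to_numpy()).any(axis=1)
    keep_cols = np.isfinite(scores.to_numpy()).any(axis=0)
    if not keep_rows.all() or not keep_cols.all():
        logger.warning("dropping %d all-missing rows and %d columns before "
                       "clustering", int((~keep_rows).sum()),
                       int((~keep_cols).sum()))
    scores = scores.loc[keep_rows, keep_cols]
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least a 2x2 score matrix to cluster")

    data = scores.to_numpy(dtype=float)
    row_link = _average_linkage(uncentred_correlation_distance(data))
    col_link = _average_linkage(uncentred_correlation_distance(data.T))

    gtr = out_prefix.with_suffix(".gtr")
    atr = out_prefix.with_suffix(".atr")
    row_ids = _write_tree(gtr, row_link, "GENE", "NODE")
    col_ids = _write_tree(atr, col_link, "ARRY", "NODE")

    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    ordered = scores.iloc[row_order, col_order]

    cdt = out_prefix.with_suffix(".cdt")
    with cdt.open("w") as fh:
        cols = list(ordered.columns)
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(map(str, cols)) + "\n")
        fh.write("AID\t\t\t\t" + "\t".join(col_ids) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1.000000"] * len(cols)) + "\n")
        for gid, (gene, row) in zip(row_ids, ordered.iterrows()):
            vals = "\t".join("" if not np.isfinite(v) else f"{v:.6f}"
                             for v in row.to_numpy())
            fh.write(f"{gid}\t{gene}\t{gene}\t1.000000\t{vals}\n")
    return {"cdt": cdt, "gtr": gtr, "atr": atr}
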