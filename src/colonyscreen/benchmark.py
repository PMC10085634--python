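"""Validation machinery: operon cosine-similarity ROC/AUC and bootstrap MAE.

Two independent checks of score quality:

* **Operon benchmark** — genes in one operon usually share function, so
  their phenotypic profiles (S-score vectors across conditions) should be
  more similar than profiles of genes from different operons.  Cosine
  similarities of same- vs different-operon gene pairs are thresholded over
  a fixed grid (-1 to 1 in steps of 0.1, 21 points) into confusion
  matrices, yielding an ROC curve and its AUC.

* **Bootstrap robustness** — each cell's replicate measurements are
  resampled with replacement, the full scoring pipeline is re-run, and the
  mean absolute error between mean bootstrap scores and the true scores
  summarizes how sensitive the scores are to replicate noise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring
from .iris_io import ScreenDataset

logger = logging.getLogger(__name__)

#: Cosine-similarity thresholds: 21 points from -1 to 1 in steps of 0.1.
THRESHOLD_GRID = np.round(np.linspace(-1.0, 1.0, 21), 10)

DEFAULT_NEGATIVE_RATIO = 10
DEFAULT_B = 1000


@dataclass
class OperonTable:
    """Mapping strain -> operon label (each strain in at most one operon)."""
    mapping: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OperonTable":
        table = pd.read_csv(path, sep="\t")
        if not {"gene", "operon"} <= set(table.columns):
            raise ValueError("operon table needs 'gene' and 'operon' columns")
        if table["gene"].duplicated().any():
            raise ValueError("a gene may belong to at most one operon")
        return cls(mapping=dict(zip(table["gene"], table["operon"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.mapping.items()),
                     columns=["gene", "operon"]).to_csv(path, sep="\t",
                                                        index=False)


@dataclass
class BenchmarkResult:
    """ROC table, AUC and/or bootstrap error summary."""
    roc: pd.DataFrame | None = None
    auc: float = float("nan")
    n_positive_pairs: int = 0
    n_negative_pairs: int = 0
    n_skipped_pairs: int = 0
    B: int = 0
    mae: float = float("nan")
    mae_pct_of_std: float = float("nan")


def cosine_profiles(m: scoring.SScoreMatrix, a: str, b: str,
                    min_overlap: int = 3) -> float:
    """Cosine similarity of two strains' phenotypic profiles.

    Computed over the conditions where both strains have a score; NaN when
    fewer than ``min_overlap`` conditions overlap.
    """
    scores = m.by_gene()
    va = scores.loc[a].to_numpy(dtype=float)
    vb = scores.loc[b].to_numpy(dtype=float)
    if va.ndim > 1 or vb.ndim > 1:
        raise ValueError("strain pinned at several positions; profiles are "
                         "per position — disambiguate before comparing")
    return _cosine(va, vb, min_overlap)


def _cosine(va: np.ndarray, vb: np.ndarray, min_overlap: int = 3) -> float:
    both = np.isfinite(va) & np.isfinite(vb)
    if both.sum() < min_overlap:
        return float("nan")
    x, y = va[both], vb[both]
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((x * y).sum() / denom)


def _pair_similarities(m: scoring.SScoreMatrix, operons: OperonTable,
                       negative_ratio: int | None, rng: np.random.Generator,
                       min_overlap: int):
    scores = m.by_gene()
    genes = [g for g in scores.index if g in operons.mapping]
    data = {g: scores.loc[g].to_numpy(dtype=float) for g in genes}

    positives, negatives = [], []
    for a, b in itertools.combinations(genes, 2):
        if operons.mapping[a] == operons.mapping[b]:
            positives.append((a, b))
        else:
            negatives.append((a, b))
    if not positives or not negatives:
        raise ValueError("need same-operon and different-operon pairs")
    if negative_ratio is not None and len(negatives) > negative_ratio * len(positives):
        idx = rng.choice(len(negatives), size=negative_ratio * len(positives),
                         replace=False)
        negatives = [negatives[i] for i in sorted(idx)]

    skipped = 0

    def sims(pairs):
        nonlocal skipped
        out = []
        for a, b in pairs:
            s = _cosine(data[a], data[b], min_overlap)
            if np.isnan(s):
                skipped += 1
            else:
                out.append(s)
        return np.asarray(out)

    return sims(positives), sims(negatives), skipped


def operon_roc(m: scoring.SScoreMatrix, operons: OperonTable,
               negative_ratio: int | None = DEFAULT_NEGATIVE_RATIO,
               seed: int = 0, min_overlap: int = 3) -> BenchmarkResult:
    """ROC/AUC of same-operon discrimination by profile cosine similarity.

    Positives are all same-operon gene pairs; negatives are
    different-operon pairs, subsampled to ``negative_ratio`` times the
    positives (``None`` enumerates all).  At each grid threshold a pair
    counts as called-positive when its similarity is strictly greater than
    the threshold.  AUC is the trapezoid area over the (FPR, sensitivity)
    points with (0,0) and (1,1) anchors.
    """
    rng = np.random.default_rng(seed)
    pos, neg, skipped = _pair_similarities(m, operons, negative_ratio, rng,
                                           min_overlap)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("no scorable gene pairs")
    rows = []
    for t in THRESHOLD_GRID:
        tp = int((pos > t).sum())
        fn = pos.size - tp
        fp = int((neg > t).sum())
        tn = neg.size - fp
        rows.append({
            "threshold": float(t), "TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "fpr": fp / (fp + tn),
        })
    roc = pd.DataFrame.from_records(rows)
    # sort the staircase by (FPR, sensitivity) so ties in FPR ascend
    pts = roc[["fpr", "sensitivity"]].sort_values(
        ["fpr", "sensitivity"]).to_numpy()
    fpr = np.concatenate([[0.0], pts[:, 0], [1.0]])
    sens = np.concatenate([[0.0], pts[:, 1], [1.0]])
    auc = float(np.trapezoid(sens, fpr))
    return BenchmarkResult(roc=roc, auc=auc,
                           n_positive_pairs=int(pos.size),
                           n_negative_pairs=int(neg.size),
                           n_skipped_pairs=skipped)


# ---------------------------------------------------------------------------
# bootstrap robustness

def resample_replicates(ds: ScreenDataset,
                        rng: np.random.Generator) -> ScreenDataset:
    """One bootstrap draw of a dataset.

    For every (strain position, condition) cell the non-missing replicate
    values are resampled with replacement, keeping their count; missing
    entries stay missing.  The RNG is consumed in a fixed order — conditions
    in stored column order, positions in stored row order — so a given
    generator state defines the draw exactly.
    """
    out = ds.copy()
    for condition in out.conditions:
        block = out.values.xs(condition, axis=1, level="condition",
                              drop_level=False)
        arr = block.to_numpy(dtype=float)
        for i in range(arr.shape[0]):
            obs = np.flatnonzero(np.isfinite(arr[i]))
            if obs.size == 0:
                continue
            draw = rng.integers(0, obs.size, obs.size)
            arr[i, obs] = arr[i, obs[draw]]
        out.values.loc[:, block.columns] = arr
    return out


def bootstrap_scores(ds: ScreenDataset, B: int = DEFAULT_B, seed: int = 0,
                     grouping: str = scoring.SCALE_BY_PLATE) -> BenchmarkResult:
    """Bootstrap the replicate measurements and summarize score stability.

    Replicate ``b`` uses ``numpy.random.default_rng([seed, b])``.  For each
    draw the full scoring pipeline (S-scores + IQR scaling) is re-run; the
    result reports ``MAE = mean |mean_b S_b - S_true|`` over cells observed
    in both, and that error as a percentage of the true scores' std.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    true = scoring.scale_scores(scoring.sscore_matrix(ds), grouping).scores
    true_arr = true.to_numpy(dtype=float)
    acc = np.zeros_like(true_arr)
    cnt = np.zeros_like(true_arr)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        ds_b = resample_replicates(ds, rng)
        sb = scoring.scale_scores(scoring.sscore_matrix(ds_b),
                                  grouping).scores.to_numpy(dtype=float)
        ok = np.isfinite(sb)
        acc[ok] += sb[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_b = acc / cnt
    both = np.isfinite(mean_b) & np.isfinite(true_arr)
    mae = float(np.abs(mean_b[both] - true_arr[both]).mean())
    std = float(np.nanstd(true_arr))
    return BenchmarkResult(B=B, mae=mae,
                           mae_pct_of_std=100.0 * mae / std if std else
                           float("nan"))
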