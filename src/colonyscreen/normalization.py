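"""Two-step plate normalization.

Densely pinned colony arrays grow larger along the plate edges because the
outermost colonies face less nutrient competition.  Stage 1 tests each
physical plate for this edge effect (Wilcoxon rank-sum between the outer two
rings and the plate centre) and, where present, rescales each ring so its
median matches the centre median.  Stage 2 makes plates comparable across
conditions: every plate is multiplied so that its centre mean equals the
median colony measurement of the whole dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iris_io import PlateQuant, ScreenDataset

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

RING_OUTER = 1
RING_SECOND = 2
RING_CENTRE = 0


def ring_index(rows: np.ndarray, cols: np.ndarray,
               n_rows: int, n_cols: int) -> np.ndarray:
    """Classify 1-based grid positions into outer ring (1), second ring (2)
    or centre (0).  The three classes partition any grid of at least 5x5."""
    if n_rows < 5 or n_cols < 5:
        raise ValueError("grid must be at least 5x5 to define two rings "
                         "and a non-empty centre")
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    ring1 = (rows == 1) | (rows == n_rows) | (cols == 1) | (cols == n_cols)
    ring2 = (~ring1) & ((rows == 2) | (rows == n_rows - 1)
                        | (cols == 2) | (cols == n_cols - 1))
    out = np.zeros(rows.shape, dtype=int)
    out[ring1] = RING_OUTER
    out[ring2] = RING_SECOND
    return out


def _grid_rings(n_rows: int, n_cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(1, n_rows + 1), np.arange(1, n_cols + 1),
                         indexing="ij")
    return ring_index(rr, cc, n_rows, n_cols)


def split_rings(plate: PlateQuant) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the (ring1, ring2, centre) measurement values of a plate."""
    rings = _grid_rings(plate.n_rows, plate.n_cols)
    v = plate.values
    return (v[rings == RING_OUTER], v[rings == RING_SECOND],
            v[rings == RING_CENTRE])


def edge_effect_test(
    plate_or_values: PlateQuant | tuple[np.ndarray, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, bool]:
    """Wilcoxon rank-sum test of the outer two rings against the centre.

    Accepts either a :class:`PlateQuant` or a pre-split ``(edges, centre)``
    pair of value arrays.  Returns ``(p_value, has_edge_effect)``;
    ``p_value`` is NaN when either side has fewer than 3 non-missing values
    (test not evaluable, no correction applied).
    """
    if isinstance(plate_or_values, PlateQuant):
        ring1, ring2, centre = split_rings(plate_or_values)
        edges = np.concatenate([ring1.ravel(), ring2.ravel()])
        centre = centre.ravel()
    else:
        edges, centre = (np.asarray(a, dtype=float).ravel()
                         for a in plate_or_values)
    edges = edges[np.isfinite(edges)]
    centre = centre[np.isfinite(centre)]
    if edges.size < 3 or centre.size < 3:
        return float("nan"), False
    p = float(stats.mannwhitneyu(edges, centre, alternative="two-sided").pvalue)
    return p, p <= alpha


@dataclass
class EdgeCorrection:
    """Outcome of stage-1 correction for one plate."""
    p_value: float
    corrected: bool
    ring_factors: tuple[float, float] = (1.0, 1.0)


def correct_edges(plate: PlateQuant) -> tuple[PlateQuant, tuple[float, float]]:
    """Equalize ring medians to the centre median.

    Every colony in ring k (k = 1 outermost, 2 next) is multiplied by
    ``median(centre) / median(ring k)``; centre colonies are untouched.
    A ring whose median is zero is left uncorrected with a warning.
    Returns the corrected plate and the two ring factors.
    """
    rings = _grid_rings(plate.n_rows, plate.n_cols)
    out = plate.copy()
    centre_med = np.nanmedian(plate.values[rings == RING_CENTRE])
    factors = []
    for k in (RING_OUTER, RING_SECOND):
        ring_vals = plate.values[rings == k]
        med = np.nanmedian(ring_vals)
        if not np.isfinite(med) or med == 0:
            logger.warning(
                "plate %s: ring %d median is 0 or undefined; left uncorrected",
                (plate.condition, plate.library_plate, plate.replicate), k)
            factors.append(1.0)
            continue
        f = centre_med / med
        out.values[rings == k] *= f
        factors.append(float(f))
    return out, (factors[0], factors[1])


def normalize_plate(plate: PlateQuant,
                    alpha: float = DEFAULT_ALPHA,
                    skip_edge_check: bool = False) -> tuple[PlateQuant, EdgeCorrection]:
    """Stage-1 normalization for a single plate.

    The ring correction is applied only when the edge test is significant
    at ``alpha`` (or unconditionally with ``skip_edge_check=True``, which
    mirrors always assuming an edge effect).
    """
    p, has_effect = edge_effect_test(plate, alpha=alpha)
    if has_effect or (skip_edge_check and np.isfinite(p)):
        corrected, factors = correct_edges(plate)
        return corrected, EdgeCorrection(p_value=p, corrected=True,
                                         ring_factors=factors)
    return plate.copy(), EdgeCorrection(p_value=p, corrected=False)


@dataclass
class NormalizationReport:
    """Per-plate record of both normalization stages."""
    plates: pd.DataFrame = field(default_factory=pd.DataFrame)
    dataset_median: float = float("nan")

    def to_tsv(self, path) -> None:
        out = self.plates.copy()
        out["dataset_median"] = self.dataset_median
        out.to_csv(path, sep="\t", index=False)


def _iter_physical_plates(ds: ScreenDataset):
    """Yield (condition, replicate, library_plate, row_mask) for every
    physical plate present in the dataset."""
    lib = ds.values.index.get_level_values("plate").to_numpy()
    for condition, replicate in ds.values.columns:
        for plate in ds.library_plates:
            yield condition, replicate, plate, lib == plate


def normalize_dataset(
    ds: ScreenDataset,
    alpha: float = DEFAULT_ALPHA,
    skip_edge_check: bool = False,
) -> tuple[ScreenDataset, NormalizationReport]:
    """Run both normalization stages over every physical plate.

    Stage 1 (conditional edge correction) is decided per plate; stage 2
    rescales each plate so its centre ("plate middle") mean equals the
    median of all non-missing values in the stage-1-corrected dataset.
    Missing values are ignored by all medians and means and stay missing.
    """
    out = ds.copy()
    vals = out.values
    rows = vals.index.get_level_values("row").to_numpy()
    cols = vals.index.get_level_values("column").to_numpy()
    rings = ring_index(rows, cols, ds.n_rows, ds.n_cols)

    records = []
    arr = vals.to_numpy(dtype=float)
    col_pos = {key: j for j, key in enumerate(vals.columns)}

    # stage 1: conditional per-ring median correction
    for condition, replicate, plate, mask in _iter_physical_plates(out):
        j = col_pos[(condition, replicate)]
        col = arr[:, j]
        if not np.isfinite(col[mask]).any():
            continue
        centre = col[mask & (rings == RING_CENTRE)]
        edges = col[mask & (rings != RING_CENTRE)]
        p, has_effect = edge_effect_test((edges, centre), alpha=alpha)
        factors = [1.0, 1.0]
        corrected = False
        if has_effect or (skip_edge_check and np.isfinite(p)):
            centre_med = np.nanmedian(centre)
            for i, k in enumerate((RING_OUTER, RING_SECOND)):
                sel = mask & (rings == k)
                med = np.nanmedian(col[sel]) if np.isfinite(col[sel]).any() else np.nan
                if not np.isfinite(med) or med == 0:
                    logger.warning("plate %s ring %d median 0/undefined; "
                                   "not corrected", (condition, plate, replicate), k)
                    continue
                factors[i] = float(centre_med / med)
                col[sel] = col[sel] * factors[i]
            corrected = True
        records.append({
            "condition": condition, "replicate": replicate,
            "library_plate": plate, "edge_test_p": p,
            "edge_corrected": corrected,
            "ring1_factor": factors[0], "ring2_factor": factors[1],
        })

    # stage 2: scale every plate's centre mean to the dataset median
    dataset_median = float(np.nanmedian(arr))
    for rec in records:
        j = col_pos[(rec["condition"], rec["replicate"])]
        mask = vals.index.get_level_values("plate") == rec["library_plate"]
        sel = mask.to_numpy() if hasattr(mask, "to_numpy") else mask
        centre = arr[sel & (rings == RING_CENTRE), j]
        centre_mean = np.nanmean(centre) if np.isfinite(centre).any() else np.nan
        if not np.isfinite(centre_mean) or centre_mean == 0:
            logger.warning("plate %s centre mean 0/undefined; excluded from "
                           "stage-2 scaling",
                           (rec["condition"], rec["library_plate"],
                            rec["replicate"]))
            rec["plate_scale_factor"] = float("nan")
            continue
        f = dataset_median / centre_mean
        arr[sel, j] = arr[sel, j] * f
        rec["plate_scale_factor"] = float(f)

    out.values.loc[:, :] = arr
    report = NormalizationReport(plates=pd.DataFrame.from_records(records),
                                 dataset_median=dataset_median)
    return out, report
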