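"""Epistasis calls from single- and double-knockout colony plates.

For a gene pair (A, B) screened alongside the wildtype and the double
knockout on replicate plates, each replicate yields fitness ratios against
that replicate's own wildtype:

    F_A  = size(dA) / size(WT)
    F_B  = size(dB) / size(WT)
    F_AB (observed) = size(dA dB) / size(WT)
    F_AB (expected) = F_A * F_B        # multiplicative null

A genetic interaction is a significant departure of the observed double
ratio from the multiplicative expectation: positive (alleviating) epistasis
when the double knockout is fitter than expected, negative (synergistic)
when less fit.  Significance is a one-way ANOVA between the replicate
vectors of observed and expected ratios; delta = mean(obs) - mean(exp)
gives the direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iris_io import PlateLayout, PlateQuant, WT_LABEL
from .small_screen import _t_ci, stars

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

CALL_NONE = "none"
CALL_POSITIVE = "positive"
CALL_NEGATIVE = "negative"


def double_label(a: str, b: str) -> str:
    """Layout label convention for the double knockout of genes a and b."""
    return f"{a}-{b}"


@dataclass
class GIRecord:
    """One gene pair's observed/expected double-knockout fitness ratios."""
    gene_a: str
    gene_b: str
    per_replicate: pd.DataFrame  # columns: replicate, f_a, f_b, f_ab_obs, f_ab_exp
    dropped_replicates: list[str] = field(default_factory=list)
    anova_p: float = float("nan")
    call: str = CALL_NONE

    @property
    def delta(self) -> float:
        """mean(observed) - mean(expected) double fitness ratio."""
        return float(self.per_replicate["f_ab_obs"].mean()
                     - self.per_replicate["f_ab_exp"].mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for col, label in (("f_a", "single A"), ("f_b", "single B"),
                           ("f_ab_obs", "double observed"),
                           ("f_ab_exp", "double expected")):
            vals = self.per_replicate[col].to_numpy()
            lo, hi = _t_ci(vals)
            rows.append({"ratio": label, "mean": float(vals.mean()),
                         "ci_low": lo, "ci_high": hi, "n": int(vals.size)})
        out = pd.DataFrame.from_records(rows)
        out["gene_a"] = self.gene_a
        out["gene_b"] = self.gene_b
        out["delta"] = self.delta
        out["anova_p"] = self.anova_p
        out["call"] = self.call
        return out


def _mean_colony(plate: PlateQuant, layout: PlateLayout, gene: str) -> float:
    """Mean measurement of a gene's colonies on one plate (NaN if absent).
    Several positions of the same gene are averaged."""
    sub = layout.table[(layout.table["plate"] == plate.library_plate)
                       & (layout.table["gene"] == gene)]
    if sub.empty:
        return float("nan")
    vals = plate.values[sub["row"].to_numpy(int) - 1,
                        sub["column"].to_numpy(int) - 1]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def gi_ratios(plates, layout: PlateLayout, pair: tuple[str, str],
              wt_label: str = WT_LABEL) -> GIRecord:
    """Per-replicate observed and expected double-knockout fitness ratios.

    Every replicate plate must carry WT, both singles and the double
    knockout (layout label ``A-B`` or ``B-A``).  Replicates whose WT mean
    is zero or missing are dropped with a warning; fewer than 2 surviving
    replicates is an error.
    """
    a, b = pair
    rows = []
    dropped: list[str] = []
    for plate in plates:
        wt = _mean_colony(plate, layout, wt_label)
        if not np.isfinite(wt) or wt == 0:
            logger.warning("replicate %s dropped: WT colony 0 or missing",
                           plate.replicate)
            dropped.append(plate.replicate)
            continue
        fa = _mean_colony(plate, layout, a) / wt
        fb = _mean_colony(plate, layout, b) / wt
        dbl = _mean_colony(plate, layout, double_label(a, b))
        if np.isnan(dbl):
            dbl = _mean_colony(plate, layout, double_label(b, a))
        obs = dbl / wt
        if not all(np.isfinite(v) for v in (fa, fb, obs)):
            logger.warning("replicate %s dropped: missing mutant colonies",
                           plate.replicate)
            dropped.append(plate.replicate)
            continue
        rows.append({"replicate": plate.replicate, "f_a": fa, "f_b": fb,
                     "f_ab_obs": obs, "f_ab_exp": fa * fb})
    if len(rows) < 2:
        raise ValueError(
            f"pair {pair}: only {len(rows)} usable replicate(s); need >= 2")
    return GIRecord(gene_a=a, gene_b=b,
                    per_replicate=pd.DataFrame.from_records(rows),
                    dropped_replicates=dropped)


def classify_epistasis(rec: GIRecord,
                       alpha: float = DEFAULT_ALPHA) -> GIRecord:
    """Call the interaction type from observed vs expected double ratios.

    One-way ANOVA between the replicate vectors of observed and expected
    double ratios; ``none`` unless p <= alpha, otherwise the sign of
    ``delta`` decides positive (alleviating) vs negative (synergistic).
    Zero variance on both sides is degenerate: p := 1, call ``none``.
    """
    obs = rec.per_replicate["f_ab_obs"].to_numpy()
    exp = rec.per_replicate["f_ab_exp"].to_numpy()
    if np.var(obs) == 0 and np.var(exp) == 0:
        logger.warning("pair (%s, %s): zero variance in both ratio vectors; "
                       "p := 1", rec.gene_a, rec.gene_b)
        p = 1.0
    else:
        p = float(stats.f_oneway(obs, exp).pvalue)
    rec.anova_p = p
    if p > alpha or not np.isfinite(p):
        rec.call = CALL_NONE
    elif rec.delta > 0:
        rec.call = CALL_POSITIVE
    else:
        rec.call = CALL_NEGATIVE
    return rec


def read_pairs(path) -> list[tuple[str, str]]:
    """Read a gene-pair declaration TSV with columns ``geneA``/``geneB``."""
    table = pd.read_csv(path, sep="\t")
    if not {"geneA", "geneB"} <= set(table.columns):
        raise ValueError("pair table needs 'geneA' and 'geneB' columns")
    return [(str(r.geneA), str(r.geneB)) for r in table.itertuples()]


def plot_gi(rec: GIRecord, path) -> None:
    """Bar plot of the four ratios with 95% CI error bars and star band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = rec.summary()
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(s))
    yerr = np.vstack([s["mean"] - s["ci_low"], s["ci_high"] - s["mean"]])
    yerr = np.where(np.isfinite(yerr), yerr, 0.0)
    ax.bar(x, s["mean"], yerr=yerr, capsize=4,
           color=["#888", "#aaa", "#4c72b0", "#dd8452"])
    ax.set_xticks(x)
    ax.set_xticklabels(s["ratio"], fontsize=8)
    ax.set_ylabel("fitness ratio vs WT")
    ax.set_title(f"{rec.gene_a} x {rec.gene_b}: {rec.call} "
                 f"({stars(rec.anova_p)})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
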