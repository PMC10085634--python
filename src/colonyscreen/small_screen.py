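"""Wildtype-relative fitness ratios for targeted small screens.

Small, hypothesis-driven screens test a handful of strains in one or a few
deliberately chosen conditions, so the assumption behind S-scores — that
fitness effects are normally distributed across many conditions — need not
hold.  Instead each mutant is compared directly to the wildtype pinned on
the same plate:

* per plate, ``ratio = mean(mutant colonies) / mean(WT colonies)`` for bar
  plots and heatmaps, and ``colony / mean(WT colonies)`` per colony for
  swarm plots;
* across replicate plates, the mean ratio with a Student-t 95% confidence
  interval; significance is the CI excluding 1 (bar plots) or a one-way
  ANOVA of mutant vs wildtype per-colony ratios (swarm plots).

Zeros are genuine no-growth phenotypes here and are never removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iris_io import ScreenDataset, WT_LABEL

logger = logging.getLogger(__name__)

#: Star bands: (upper p bound, label); p > 0.05 is "ns".
STAR_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance band for a p-value (ns, *, **, ***, ****)."""
    if not np.isfinite(p) or p > 0.05:
        return "ns"
    for bound, label in STAR_BANDS:
        if p <= bound:
            return label
    return "*"


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    n = values.size
    if n < 2:
        return float("nan"), float("nan")
    mean = values.mean()
    sem = values.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sem
    return float(mean - half), float(mean + half)


@dataclass
class FitnessRatioTable:
    """Per-(strain, condition) fitness ratios with uncertainty.

    ``summary`` has one row per (gene, condition) with the across-plate
    mean ratio and 95% CI; ``colonies`` holds the per-colony ratios that
    feed swarm plots and the ANOVA.
    """
    summary: pd.DataFrame
    colonies: pd.DataFrame
    excluded_plates: list[tuple] | None = None

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)

    def heatmap_matrix(self) -> pd.DataFrame:
        return self.summary.pivot(index="gene", columns="condition",
                                  values="mean_ratio")


def fitness_ratios(ds: ScreenDataset,
                   wt_label: str = WT_LABEL) -> FitnessRatioTable:
    """Compute per-plate and per-colony wildtype-relative fitness ratios.

    Each physical plate's denominator is the mean of its own (pooled) WT
    colonies; plates without a WT colony, or with WT mean 0, are excluded
    with a warning.  Per-strain plate ratios are then averaged across
    replicate plates with a t-based 95% CI.
    """
    genes = ds.values.index.get_level_values("gene")
    lib = ds.values.index.get_level_values("plate").to_numpy()
    if wt_label not in set(genes):
        raise ValueError(f"wildtype label {wt_label!r} not in layout")

    plate_rows = []
    colony_rows = []
    excluded = []
    for condition, replicate in ds.values.columns:
        col = ds.values[(condition, replicate)].to_numpy(dtype=float)
        for plate in ds.library_plates:
            on_plate = lib == plate
            wt_vals = col[on_plate & (genes == wt_label)]
            wt_vals = wt_vals[np.isfinite(wt_vals)]
            if wt_vals.size == 0 or wt_vals.mean() == 0:
                if np.isfinite(col[on_plate]).any():
                    excluded.append((condition, replicate, plate))
                    logger.warning("plate %s excluded: no usable WT colonies",
                                   (condition, replicate, plate))
                continue
            wt_mean = wt_vals.mean()
            for gene in pd.unique(genes[on_plate]):
                sel = on_plate & (genes == gene)
                vals = col[sel]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    continue
                plate_rows.append({
                    "gene": gene, "condition": condition,
                    "replicate": replicate, "plate": plate,
                    "plate_ratio": float(vals.mean() / wt_mean),
                })
                for v in vals:
                    colony_rows.append({
                        "gene": gene, "condition": condition,
                        "replicate": replicate, "plate": plate,
                        "ratio": float(v / wt_mean),
                    })
    if not plate_rows:
        raise ValueError("no plate carried usable wildtype colonies")
    per_plate = pd.DataFrame.from_records(plate_rows)
    colonies = pd.DataFrame.from_records(colony_rows)

    rows = []
    for (gene, condition), grp in per_plate.groupby(["gene", "condition"],
                                                    sort=False):
        ratios = grp["plate_ratio"].to_numpy()
        lo, hi = _t_ci(ratios)
        rows.append({
            "gene": gene, "condition": condition,
            "mean_ratio": float(ratios.mean()),
            "ci_low": lo, "ci_high": hi, "n_plates": int(ratios.size),
        })
    summary = pd.DataFrame.from_records(rows)
    return FitnessRatioTable(summary=summary, colonies=colonies,
                             excluded_plates=excluded)


def significance(table: FitnessRatioTable,
                 wt_label: str = WT_LABEL) -> FitnessRatioTable:
    """Attach significance to a fitness-ratio table.

    ``ci_excludes_wt``: the mutant's 95% CI excludes the wildtype mean
    ratio of 1 (bar-plot criterion).  ``anova_p``: one-way ANOVA of the
    mutant's per-colony ratios against the wildtype's, per condition
    (swarm-plot criterion), with the matching star band.  When both groups
    are degenerate (zero variance) p is reported as 1 with a warning.
    """
    summary = table.summary.copy()
    ps, star_col, ci_flag = [], [], []
    for _, row in summary.iterrows():
        gene, condition = row["gene"], row["condition"]
        mut = table.colonies.query("gene == @gene and condition == @condition")
        wt = table.colonies.query("gene == @wt_label and condition == @condition")
        x = mut["ratio"].to_numpy()
        y = wt["ratio"].to_numpy()
        if gene == wt_label or x.size < 2 or y.size < 2:
            p = float("nan")
        elif np.var(x) == 0 and np.var(y) == 0:
            logger.warning("(%s, %s): both groups zero-variance; p := 1",
                           gene, condition)
            p = 1.0
        else:
            p = float(stats.f_oneway(x, y).pvalue)
        ps.append(p)
        star_col.append(stars(p))
        lo, hi = row["ci_low"], row["ci_high"]
        ci_flag.append(bool(np.isfinite(lo) and (lo > 1.0 or hi < 1.0)))
    summary["anova_p"] = ps
    summary["stars"] = star_col
    summary["ci_excludes_wt"] = ci_flag
    return FitnessRatioTable(summary=summary, colonies=table.colonies,
                             excluded_plates=table.excluded_plates)


# ---------------------------------------------------------------------------
# plots

def plot_bars(table: FitnessRatioTable, path, wt_label: str = WT_LABEL) -> None:
    """Bar plot of mean fitness ratios with 95% CI error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    s = table.summary[table.summary["gene"] != wt_label]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(s), 4))
    x = np.arange(len(s))
    yerr = np.vstack([s["mean_ratio"] - s["ci_low"],
                      s["ci_high"] - s["mean_ratio"]])
    yerr = np.where(np.isfinite(yerr), yerr, 0.0)
    ax.bar(x, s["mean_ratio"], yerr=yerr, capsize=4,
           color=sns.color_palette("deep", max(len(s), 1)))
    ax.axhline(1.0, ls="--", c="grey", lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels([f"{g}\n{c}" for g, c in zip(s["gene"], s["condition"])],
                       fontsize=8)
    ax.set_ylabel("fitness ratio (mutant / WT)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_swarm(table: FitnessRatioTable, path) -> None:
    """Swarm plot of per-colony fitness ratios by strain and condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    d = table.colonies.copy()
    d["group"] = d["gene"] + " | " + d["condition"]
    fig, ax = plt.subplots(figsize=(1.5 + 0.8 * d["group"].nunique(), 4))
    sns.swarmplot(data=d, x="group", y="ratio", hue="gene", size=3,
                  legend=False, ax=ax)
    ax.axhline(1.0, ls="--", c="grey", lw=1)
    ax.set_ylabel("per-colony fitness ratio")
    ax.tick_params(axis="x", labelsize=7, rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(table: FitnessRatioTable, path) -> None:
    """Strain x condition heatmap of mean fitness ratios."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    mat = table.heatmap_matrix()
    fig, ax = plt.subplots(figsize=(1.5 + 0.7 * mat.shape[1],
                                    1.0 + 0.4 * mat.shape[0]))
    sns.heatmap(mat, annot=True, fmt=".2f", cmap="vlag", center=1.0, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
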