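"""Synthetic colony-screen generator with known ground truth.

Emulates the data regimes of a real arrayed chemical-genomic screen so that
every pipeline stage can be exercised without external raw data:

* log-normal base colony sizes (positive, right-skewed) with per-strain
  variation and per-colony replicate noise, all multiplicative — the same
  structure the normalization and scoring steps assume;
* multiplicative edge effects on the outer two rings of each plate;
* per-plate scale differences across conditions and replicates;
* missing positions and mis-pinned colonies (literal zero measurements,
  exercising the stray-zero curation rule);
* injected gene x condition fitness effects, optionally organised into
  operon groups whose members share correlated effect profiles;
* single/double-knockout plate designs with a controllable departure from
  the multiplicative epistasis null;
* a mislabelled-plate scenario (two plates' condition labels swapped).

Identical configuration + seed reproduces the output byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .iris_io import (EMPTY_LABEL, WT_LABEL, PlateLayout, PlateQuant,
                      build_dataset, layout_from_mapping)


def _lognormal(rng: np.random.Generator, median: float, cv: float, size):
    """Log-normal draws parameterized by median and coefficient of variation."""
    if cv <= 0:
        return np.full(size, float(median))
    sigma = np.sqrt(np.log1p(cv ** 2))
    return median * np.exp(rng.normal(0.0, sigma, size))


@dataclass
class SimulationConfig:
    """Study design for a simulated screen.

    Defaults model a routine 1536-density screen: ~1200-unit median colony
    size with 25% strain-to-strain spread, a pronounced edge effect (outer
    ring 1.5x, second ring 1.2x), 15% plate-to-plate scale jitter, 10%
    replicate noise, and sparse missing/mis-pinned positions.
    """
    n_rows: int = 32
    n_cols: int = 48
    n_conditions: int = 3
    n_replicates: int = 3
    n_library_plates: int = 1
    base_median: float = 1200.0
    base_cv: float = 0.25
    edge_multipliers: tuple[float, float] = (1.5, 1.2)
    plate_scale_cv: float = 0.15
    noise_cv: float = 0.10
    missing_prob: float = 0.005
    mispin_prob: float = 0.005
    #: (gene, condition) -> fitness multiplier (> 0; 0 = no growth).
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    #: operon label -> member genes; members share correlated log-effect
    #: profiles with correlation ``operon_rho`` and log-sd ``operon_sd``.
    operons: dict[str, list[str]] = field(default_factory=dict)
    operon_rho: float = 0.9
    operon_sd: float = 0.5
    condition_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("missing_prob", self.missing_prob),
                        ("mispin_prob", self.mispin_prob)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(m <= 0 for m in self.edge_multipliers):
            raise ValueError("edge multipliers must be > 0")
        if any(m < 0 for m in self.effects.values()):
            raise ValueError("fitness multipliers must be >= 0")
        if not (0 <= self.operon_rho <= 1):
            raise ValueError("operon_rho must be in [0, 1]")

    @property
    def conditions(self) -> list[str]:
        if self.condition_names is not None:
            if len(self.condition_names) != self.n_conditions:
                raise ValueError("condition_names length mismatch")
            return list(self.condition_names)
        return [f"cond{i + 1:02d}" for i in range(self.n_conditions)]

    @property
    def replicate_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_replicates)]


@dataclass
class SimulatedScreen:
    """In-memory result of a simulation: plates, layout and ground truth."""
    plates: list[PlateQuant]
    layout: PlateLayout
    truth: pd.DataFrame  # columns gene, condition, multiplier
    config: SimulationConfig

    def dataset(self):
        return build_dataset(self.plates, self.layout)

    def write(self, out_dir: str | Path) -> dict[str, object]:
        """Write Iris files, the layout TSV and the effect-truth TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        iris_paths = [write_iris_file(p, out_dir) for p in self.plates]
        layout_path = out_dir / "layout.tsv"
        self.layout.to_tsv(layout_path)
        truth_path = out_dir / "effects_truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {"iris": iris_paths, "layout": layout_path,
                "truth": truth_path}

    def sha256(self) -> str:
        """Digest of all generated content (determinism check)."""
        h = hashlib.sha256()
        for p in sorted(self.plates, key=lambda q: q.key):
            h.update(repr(p.key).encode())
            h.update(np.ascontiguousarray(p.values).tobytes())
        h.update(self.layout.table.to_csv(index=False).encode())
        h.update(self.truth.to_csv(index=False).encode())
        return h.hexdigest()


def write_iris_file(plate: PlateQuant, out_dir: Path) -> Path:
    """Write one plate in the Iris tab-separated dialect.

    The opacity column is a fixed multiple of size — enough to exercise
    measurement-column selection without a second phenotype model.
    """
    name = f"{plate.condition}-{plate.library_plate}_{plate.replicate}.iris"
    path = Path(out_dir) / name
    lines = [
        "# Iris-format colony quantification (synthetic)",
        f"# condition: {plate.condition}  plate: {plate.library_plate}  "
        f"replicate: {plate.replicate}",
        "row\tcolumn\tsize\tcircularity\tcolony integral opacity",
    ]
    for r in range(plate.n_rows):
        for c in range(plate.n_cols):
            v = plate.values[r, c]
            if not np.isfinite(v):
                continue  # missing positions are simply absent from the file
            lines.append(f"{r + 1}\t{c + 1}\t{v:.4f}\t0.9500\t{35 * v:.4f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _ring_multiplier_grid(cfg: SimulationConfig) -> np.ndarray:
    from .normalization import RING_OUTER, RING_SECOND, _grid_rings
    rings = _grid_rings(cfg.n_rows, cfg.n_cols)
    grid = np.ones((cfg.n_rows, cfg.n_cols))
    grid[rings == RING_OUTER] = cfg.edge_multipliers[0]
    grid[rings == RING_SECOND] = cfg.edge_multipliers[1]
    return grid


def default_gene_names(cfg: SimulationConfig) -> list[str]:
    n = cfg.n_library_plates * cfg.n_rows * cfg.n_cols
    return [f"gene{i + 1:04d}" for i in range(n)]


def _make_layout(cfg: SimulationConfig, genes: list[str]) -> PlateLayout:
    mapping = {}
    i = 0
    for plate in range(1, cfg.n_library_plates + 1):
        for r in range(1, cfg.n_rows + 1):
            for c in range(1, cfg.n_cols + 1):
                mapping[(plate, r, c)] = genes[i]
                i += 1
    return layout_from_mapping(mapping)


def _operon_effects(cfg: SimulationConfig,
                    rng: np.random.Generator) -> dict[tuple[str, str], float]:
    """Correlated log-normal effect profiles for operon members."""
    out: dict[tuple[str, str], float] = {}
    conditions = cfg.conditions
    rho, sd = cfg.operon_rho, cfg.operon_sd
    for operon in sorted(cfg.operons):
        shared = rng.normal(0.0, 1.0, len(conditions))
        for gene in cfg.operons[operon]:
            own = rng.normal(0.0, 1.0, len(conditions))
            log_eff = sd * (rho * shared + np.sqrt(1 - rho ** 2) * own)
            for c, le in zip(conditions, log_eff):
                out[(gene, c)] = float(np.exp(le))
    return out


def simulate_big(cfg: SimulationConfig,
                 genes: list[str] | None = None) -> SimulatedScreen:
    """Simulate a large screen: one plate per condition x replicate x
    library plate.

    Colony size = strain base x plate scale x ring multiplier x injected
    effect x replicate noise; mis-pins overwrite with a literal 0 and
    missing positions are dropped from the written file.
    """
    rng = np.random.default_rng(cfg.seed)
    if genes is None:
        genes = default_gene_names(cfg)
    layout = _make_layout(cfg, genes)
    ring_grid = _ring_multiplier_grid(cfg)
    base = dict(zip(genes, _lognormal(rng, cfg.base_median, cfg.base_cv,
                                      len(genes))))

    effects = dict(_operon_effects(cfg, rng))
    effects.update(cfg.effects)  # explicit effects take precedence

    gene_grid: list[np.ndarray] = []
    for plate in range(1, cfg.n_library_plates + 1):
        sub = np.array(genes[(plate - 1) * cfg.n_rows * cfg.n_cols:
                             plate * cfg.n_rows * cfg.n_cols])
        gene_grid.append(sub.reshape(cfg.n_rows, cfg.n_cols))

    plates: list[PlateQuant] = []
    for condition in cfg.conditions:
        for replicate in cfg.replicate_labels:
            for plate_no in range(1, cfg.n_library_plates + 1):
                gg = gene_grid[plate_no - 1]
                scale = float(_lognormal(rng, 1.0, cfg.plate_scale_cv, ()))
                base_grid = np.vectorize(base.__getitem__)(gg)
                eff_grid = np.vectorize(
                    lambda g: effects.get((g, condition), 1.0))(gg)
                noise = _lognormal(rng, 1.0, cfg.noise_cv,
                                   (cfg.n_rows, cfg.n_cols))
                values = base_grid * scale * ring_grid * eff_grid * noise
                mispin = rng.random((cfg.n_rows, cfg.n_cols)) < cfg.mispin_prob
                values[mispin] = 0.0
                missing = rng.random((cfg.n_rows, cfg.n_cols)) < cfg.missing_prob
                values[missing] = np.nan
                plates.append(PlateQuant(
                    condition=condition, library_plate=plate_no,
                    replicate=replicate, values=values))

    truth = pd.DataFrame.from_records(
        [{"gene": g, "condition": c, "multiplier": m}
         for (g, c), m in sorted(effects.items())],
        columns=["gene", "condition", "multiplier"])
    return SimulatedScreen(plates=plates, layout=layout, truth=truth,
                           config=cfg)


def simulate_small(cfg: SimulationConfig, n_mutants: int = 5,
                   wt_fraction: float = 0.25) -> SimulatedScreen:
    """Simulate a targeted small screen with pooled wildtype positions.

    Roughly ``wt_fraction`` of each plate's positions (interleaved) carry
    the wildtype; the rest cycle through ``n_mutants`` mutant strains.
    Effects with multiplier 0 yield exact zero colonies on every replicate
    — a true no-growth phenotype the small pipeline must keep.

    Mutants share the wildtype's base size (``base_cv`` is ignored): in a
    targeted screen of isogenic knockouts any baseline growth difference is
    itself the phenotype, so it belongs to the injected effect table, and
    the injected multipliers are then the ground-truth fitness ratios.
    """
    cfg = replace(cfg, base_cv=0.0)
    mutants = [f"mut{i + 1:02d}" for i in range(n_mutants)]
    n_pos = cfg.n_library_plates * cfg.n_rows * cfg.n_cols
    stride = max(int(round(1 / wt_fraction)), 2)
    genes = [WT_LABEL if i % stride == 0 else mutants[i % len(mutants)]
             for i in range(n_pos)]
    sim = simulate_big(cfg, genes=genes)
    # zero-growth effects must be exactly zero, not lognormal-noised
    for (gene, condition), mult in cfg.effects.items():
        if mult == 0.0:
            for plate in sim.plates:
                if plate.condition != condition:
                    continue
                gg = sim.layout.table[
                    (sim.layout.table["plate"] == plate.library_plate)
                    & (sim.layout.table["gene"] == gene)]
                plate.values[gg["row"].to_numpy(int) - 1,
                             gg["column"].to_numpy(int) - 1] = 0.0
    return sim


@dataclass
class GISimulationConfig:
    """Design for a single/double-knockout epistasis plate series."""
    gene_a: str = "geneA"
    gene_b: str = "geneB"
    f_a: float = 0.5            # single-knockout fitness ratios
    f_b: float = 0.6
    epistasis_offset: float = 0.0  # double = WT * f_a * f_b * (1 + offset)
    n_replicates: int = 6
    colonies_per_genotype: int = 6
    base_median: float = 1000.0
    noise_cv: float = 0.10
    condition: str = "GI"
    seed: int = 0


def simulate_gi(cfg: GISimulationConfig) -> SimulatedScreen:
    """Simulate replicate plates carrying WT, both singles and the double.

    Each genotype occupies one row of a ``4 x colonies_per_genotype`` grid.
    Grids smaller than 5x5 are fine here: GI plates are not normalized.
    """
    from .genetic_interactions import double_label
    rng = np.random.default_rng(cfg.seed)
    genotypes = [WT_LABEL, cfg.gene_a, cfg.gene_b,
                 double_label(cfg.gene_a, cfg.gene_b)]
    mult = {WT_LABEL: 1.0, cfg.gene_a: cfg.f_a, cfg.gene_b: cfg.f_b,
            genotypes[3]: cfg.f_a * cfg.f_b * (1.0 + cfg.epistasis_offset)}
    mapping = {(1, r + 1, c + 1): genotypes[r]
               for r in range(4) for c in range(cfg.colonies_per_genotype)}
    layout = layout_from_mapping(mapping)

    plates = []
    for replicate in [chr(ord("A") + i) for i in range(cfg.n_replicates)]:
        values = np.full((4, cfg.colonies_per_genotype), np.nan)
        wt_base = float(_lognormal(rng, cfg.base_median, cfg.noise_cv, ()))
        for r, genotype in enumerate(genotypes):
            values[r] = wt_base * mult[genotype] * _lognormal(
                rng, 1.0, cfg.noise_cv, cfg.colonies_per_genotype)
        plates.append(PlateQuant(condition=cfg.condition, library_plate=1,
                                 replicate=replicate, values=values))
    truth = pd.DataFrame.from_records([
        {"gene": g, "condition": cfg.condition, "multiplier": mult[g]}
        for g in genotypes])
    big_cfg = SimulationConfig(n_rows=4, n_cols=cfg.colonies_per_genotype,
                               n_conditions=1, n_replicates=cfg.n_replicates,
                               edge_multipliers=(1.0, 1.0), seed=cfg.seed)
    return SimulatedScreen(plates=plates, layout=layout, truth=truth,
                           config=big_cfg)


def swap_condition_labels(plates: list[PlateQuant],
                          key_a: tuple[str, int, str],
                          key_b: tuple[str, int, str]) -> list[PlateQuant]:
    """Mislabelled-plate scenario: swap two plates' condition labels."""
    out = [p.copy() for p in plates]
    by_key = {p.key: p for p in out}
    pa, pb = by_key[key_a], by_key[key_b]
    pa.condition, pb.condition = pb.condition, pa.condition
    return out
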