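"""Synthetic parent/hybrid count matrices with planted category structure.

The generator emulates the study design this pipeline targets: three
genotype groups (paternal, maternal, hybrid) × three replicate libraries,
negative-binomial read counts, and genes planted in each of the twelve
expression categories plus NoChange, Silenced and Novel.

Per gene, a baseline maternal mean RPKM is drawn log-normally; the
paternal mean is set equal or ±effect_lfc log2 units away according to
the planted category; the hybrid mean follows the category geometry
(matching parent for dominance, geometric mid-point for mid-parent —
placing the hybrid effect_lfc/2 from each parent so that planted
mid-parent genes are separable from both parents whenever
effect_lfc > 2*tau — beyond the extreme parent by effect_lfc for
transgressive genes).  The geometry is expressed at the dosage-compensated
(diploid) state; ``dosage_factor`` rescales all hybrid means relative to
the additive triploid expectation under equal parental expression
(hybrid mean × dosage_factor × 3/2), so the default 2/3 — full
compensation to the diploid state — leaves the planted geometry exact,
while 1.0 simulates an uncompensated triploid.

Expected RPKM is converted to an expected per-replicate count via
count = RPKM × N × L / 1e9 and counts are drawn NB(mean μ, variance
μ + dispersion·μ²); dispersion 0 falls back to Poisson.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import ROMAN
from .io import ExpressionMatrix, GeneRecord

DEFAULT_PROPORTIONS = {
    **{c.value: 0.03 for c in ROMAN},
    "NoChange": 0.60,
    "Silenced": 0.02,
    "Novel": 0.02,
}

PLANTABLE = tuple(c.value for c in ROMAN) + ("NoChange", "Silenced", "Novel")

# Parents: +1 → paternal above maternal by effect_lfc, -1 → below, 0 → equal.
_PARENT_SIGN = {
    "I": +1, "V": +1, "VII": +1, "IX": +1, "XI": +1,
    "II": -1, "VI": -1, "VIII": -1, "X": -1, "XII": -1,
    "III": 0, "IV": 0, "NoChange": 0,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the targeted design: 3 replicates per genotype at a
    depth of 1e6 mapped reads, log-normal baseline expression (median
    ~20 RPKM, sigma 1 on the log scale), planted effects of 3 log2 units,
    NB dispersion 0.05, gene lengths uniform on 400–4000 bp, and full
    dosage compensation (factor 2/3).
    """

    n_genes: int = 2000
    category_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    base_mean_rpkm: tuple[float, float] = (math.log(20.0), 1.0)  # log-normal (mu, sigma)
    effect_lfc: float = 3.0
    dispersion: float = 0.05
    library_size: int = 1_000_000
    replicates: int = 3
    gene_length_range: tuple[int, int] = (400, 4000)
    dosage_factor: float = 2.0 / 3.0
    floor_rpkm: float = 10.0  # silencing/novel floor the planted genes must clear
    tau: float = 1.0  # classification threshold the geometry must beat
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.category_proportions) - set(PLANTABLE)
        if unknown:
            raise ValueError(f"unknown categories in proportions: {sorted(unknown)}")
        total = sum(self.category_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"category proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ValueError("category proportions must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates < 1 or self.n_genes < 1 or self.library_size < 1:
            raise ValueError("n_genes, replicates and library_size must be >= 1")
        self.feasible = self.effect_lfc > 2 * self.tau
        if not self.feasible:
            # mid-parent genes cannot be separated from both parents
            import warnings

            warnings.warn(
                f"effect_lfc={self.effect_lfc} <= 2*tau={2 * self.tau}: planted "
                "mid-parent geometry is not recoverable at this threshold",
                stacklevel=2,
            )


def _category_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_genes over the proportions."""
    raw = {c: config.category_proportions.get(c, 0.0) * config.n_genes for c in PLANTABLE}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _plant_means(category: str, baseline: float, config: SimulationConfig
                 ) -> tuple[float, float, float]:
    """(paternal, maternal, hybrid) expected RPKM before dosage scaling."""
    fold = 2.0 ** config.effect_lfc
    high_parent = max(config.floor_rpkm * 4.0, baseline)
    if category == "Silenced":
        return high_parent, high_parent, 0.0
    if category == "Novel":
        return 0.0, 0.0, high_parent
    g = baseline
    sign = _PARENT_SIGN[category]
    b = g * fold if sign > 0 else (g / fold if sign < 0 else g)
    low, high = min(b, g), max(b, g)
    if category in ("I", "II", "III"):
        h = low / fold
    elif category in ("IV", "V", "VI"):
        h = high * fold
    elif category in ("VII", "VIII"):
        h = b
    elif category in ("IX", "X"):
        h = g
    elif category in ("XI", "XII"):
        h = math.sqrt(b * g)
    else:  # NoChange
        h = g
    return b, g, h


def generate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a synthetic count matrix plus its ground truth.

    Returns the :class:`ExpressionMatrix` (library sizes fixed at the
    nominal depth) and a truth table with columns ``gene_id``,
    ``category``, ``chi_paternal``, ``chi_maternal``, ``hybrid_expected``
    (post dosage scaling) and ``length_bp``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts_by_cat = _category_counts(config)
    categories = [c for c, k in counts_by_cat.items() for _ in range(k)]
    rng.shuffle(categories)

    mu_log, sigma_log = config.base_mean_rpkm
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    baselines = rng.lognormal(mean=mu_log, sigma=sigma_log, size=config.n_genes)
    hybrid_scale = config.dosage_factor * 1.5  # 1.0 at full compensation

    genes, truth_rows = [], []
    mean_rpkm = np.empty((config.n_genes, 3))  # paternal, maternal, hybrid
    for i, (category, baseline, length) in enumerate(zip(categories, baselines, lengths)):
        b, g, h = _plant_means(category, float(baseline), config)
        h *= hybrid_scale
        gene_id = f"gene{i + 1:05d}"
        genes.append(GeneRecord(gene_id, int(length)))
        mean_rpkm[i] = (b, g, h)
        truth_rows.append({"gene_id": gene_id, "category": category,
                           "chi_paternal": b, "chi_maternal": g,
                           "hybrid_expected": h, "length_bp": int(length)})

    samples, group_of, mu_cols = [], {}, []
    for group, col in (("paternal", 0), ("maternal", 1), ("hybrid", 2)):
        for r in range(1, config.replicates + 1):
            name = f"{group}_{r}"
            samples.append(name)
            group_of[name] = group
            mu_cols.append(mean_rpkm[:, col] * config.library_size
                           * lengths / 1e9)
    mu = np.column_stack(mu_cols)

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / config.dispersion
        p_param = 1.0 / (1.0 + config.dispersion * mu)
        counts = rng.negative_binomial(n_param, p_param)

    matrix = ExpressionMatrix(
        genes=genes, samples=samples, group_of=group_of,
        counts=counts.astype(np.int64),
        library_size=np.full(len(samples), config.library_size, dtype=np.int64),
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["feasible"] = config.feasible
    return matrix, truth


def recovery_score(truth: pd.DataFrame, assignments) -> float:
    """Fraction of genes whose assigned category equals the planted one.

    Ambiguous/Unresolved/Excluded assignments count as misses unless
    planted as such (they never are).
    """
    assigned = {a.gene_id: a.category.value for a in assignments}
    if set(assigned) != set(truth["gene_id"]):
        raise ValueError("assignments and truth cover different gene sets")
    hits = sum(assigned[row.gene_id] == row.category for row in truth.itertuples())
    return hits / len(truth)
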