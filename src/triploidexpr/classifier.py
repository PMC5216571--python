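"""Twelve-category expression classification for a parent/hybrid trio.

Each gene is placed in one of twelve states (Roman numerals) from three
pairwise comparisons of mean expression: parents against each other (P),
hybrid against the paternal parent (Hb) and hybrid against the maternal
parent (Hg).  The groupings are

* I–III   — transgressive down (hybrid below both parents)
* IV–VI   — transgressive up (hybrid above both parents)
* VII/VIII — paternal expression-level dominance (hybrid matches father)
* IX/X    — maternal expression-level dominance (hybrid matches mother)
* XI/XII  — mid-parent (hybrid strictly between distinct parents)

In the default RPKM-threshold mode a pair is "equal" when the absolute
log2 ratio is ≤ tau (non-strict, default 1.0) and "higher"/"lower"
otherwise; this non-strict equality reproduces borderline published
labels (ratios 0.986 and 1.075 fall on opposite sides of tau = 1).
Silencing (hybrid zero while both parents exceed an RPKM floor) and novel
expression (both parents zero while the hybrid exceeds the floor) are
detected before ratio classification; remaining genes with any zero group
mean are Excluded rather than pseudocounted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GroupExpression


class Category(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"
    XI = "XI"
    XII = "XII"
    NO_CHANGE = "NoChange"
    AMBIGUOUS = "Ambiguous"
    UNRESOLVED = "Unresolved"
    SILENCED = "Silenced"
    NOVEL = "Novel"
    EXCLUDED = "Excluded"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


ROMAN = tuple(Category(v) for v in
              ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"))

GROUPINGS: dict[str, frozenset[Category]] = {
    "down": frozenset({Category.I, Category.II, Category.III}),
    "up": frozenset({Category.IV, Category.V, Category.VI}),
    "paternalELD": frozenset({Category.VII, Category.VIII}),
    "maternalELD": frozenset({Category.IX, Category.X}),
    "mid": frozenset({Category.XI, Category.XII}),
}

# Parental-role swap maps category pairs onto each other; III, IV and the
# non-numeral states are fixed points.
MIRROR: dict[Category, Category] = {
    Category.I: Category.II, Category.II: Category.I,
    Category.V: Category.VI, Category.VI: Category.V,
    Category.VII: Category.X, Category.X: Category.VII,
    Category.VIII: Category.IX, Category.IX: Category.VIII,
    Category.XI: Category.XII, Category.XII: Category.XI,
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables for the category classifier.

    tau — log2-ratio half-width of the equality band (default 1.0).
    mode — ``rpkm-threshold`` (default) or ``statistical`` (calls taken
    from pre-computed differential-expression results).
    silent_novel_min — RPKM floor for silencing/novel detection (default 10).
    ambiguous_tiebreak — resolve hybrid-equal-to-both cases toward the
    parent with the smaller absolute log2 ratio instead of labelling them
    Ambiguous.
    """

    tau: float = 1.0
    mode: str = "rpkm-threshold"
    silent_novel_min: float = 10.0
    ambiguous_tiebreak: bool = False

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.silent_novel_min <= 0:
            raise ValueError(f"silent_novel_min must be > 0, got {self.silent_novel_min}")
        if self.mode not in ("rpkm-threshold", "statistical"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PairwiseCall:
    """One pairwise comparison: higher/lower/equal plus its evidence."""

    value: str  # "higher" | "lower" | "equal"
    log2_ratio: float
    q_value: float | None = None


@dataclass
class CategoryAssignment:
    """Final per-gene label with the three underlying pairwise calls."""

    gene_id: str
    category: Category
    call_parents: str | None = None
    call_hybrid_paternal: str | None = None
    call_hybrid_maternal: str | None = None
    chi_paternal: float | None = None
    chi_maternal: float | None = None
    at_elv: float | None = None


def pairwise_call(x: float, y: float, config: ClassifierConfig | None = None) -> PairwiseCall:
    """Compare two expression levels: equal iff |log2(x/y)| <= tau."""
    config = config or ClassifierConfig()
    if x <= 0 or y <= 0:
        raise ValueError(
            "pairwise_call requires strictly positive expression; "
            "route zero-expression genes to silencing/novel/Excluded first"
        )
    ratio = math.log2(x / y)
    if abs(ratio) <= config.tau:
        value = "equal"
    else:
        value = "higher" if ratio > 0 else "lower"
    return PairwiseCall(value=value, log2_ratio=ratio)


def detect_silenced(chi_paternal: float, chi_maternal: float, at_elv: float,
                    config: ClassifierConfig | None = None) -> bool:
    """Hybrid silent: zero hybrid expression, both parents above the floor."""
    config = config or ClassifierConfig()
    return (at_elv == 0 and chi_paternal > config.silent_novel_min
            and chi_maternal > config.silent_novel_min)


def detect_novel(chi_paternal: float, chi_maternal: float, at_elv: float,
                 config: ClassifierConfig | None = None) -> bool:
    """Novel expression: both parents zero, hybrid above the floor."""
    config = config or ClassifierConfig()
    return chi_paternal == 0 and chi_maternal == 0 and at_elv > config.silent_novel_min


def _decide(p: str, hb: str, hg: str) -> Category:
    """Decision table mapping the call triple (P, Hb, Hg) to a category.

    Patterns are the exclusive geometric ones (e.g. transgressive up means
    the hybrid is above BOTH parents).  In threshold mode every reachable
    triple matches a pattern; independent statistical tests can break
    transitivity and produce unreachable combinations, which are reported
    as Unresolved rather than silently merged.
    """
    if p == "higher":  # paternal above maternal
        if hb == "higher" and hg == "higher":
            return Category.V
        if hb == "lower" and hg == "lower":
            return Category.I
        if hb == "equal" and hg == "higher":
            return Category.VII
        if hg == "equal" and hb == "lower":
            return Category.IX
        if hb == "lower" and hg == "higher":
            return Category.XI
        if hb == "equal" and hg == "equal":
            return Category.AMBIGUOUS
        return Category.UNRESOLVED
    if p == "lower":  # maternal above paternal
        if hb == "higher" and hg == "higher":
            return Category.VI
        if hb == "lower" and hg == "lower":
            return Category.II
        if hb == "equal" and hg == "lower":
            return Category.VIII
        if hg == "equal" and hb == "higher":
            return Category.X
        if hb == "higher" and hg == "lower":
            return Category.XII
        if hb == "equal" and hg == "equal":
            return Category.AMBIGUOUS
        return Category.UNRESOLVED
    # parents not distinguishable
    if hb == "higher" and hg == "higher":
        return Category.IV
    if hb == "lower" and hg == "lower":
        return Category.III
    return Category.NO_CHANGE


def _tiebreak(p: str, rb: float, rg: float) -> Category:
    """Optional Ambiguous resolution toward the closer parent."""
    if abs(rb) == abs(rg):
        return Category.AMBIGUOUS
    toward_paternal = abs(rb) < abs(rg)
    if p == "higher":
        return Category.VII if toward_paternal else Category.IX
    return Category.X if toward_paternal else Category.VIII


def classify_gene(chi_paternal: float, chi_maternal: float, at_elv: float,
                  config: ClassifierConfig | None = None) -> CategoryAssignment:
    """Classify one strictly positive (paternal, maternal, hybrid) triple."""
    config = config or ClassifierConfig()
    if chi_paternal <= 0 or chi_maternal <= 0 or at_elv <= 0:
        raise ValueError("classify_gene requires strictly positive levels; "
                         "handle Silenced/Novel/Excluded upstream")
    p = pairwise_call(chi_paternal, chi_maternal, config)
    hb = pairwise_call(at_elv, chi_paternal, config)
    hg = pairwise_call(at_elv, chi_maternal, config)
    category = _decide(p.value, hb.value, hg.value)
    if (category is Category.AMBIGUOUS and config.ambiguous_tiebreak):
        category = _tiebreak(p.value, hb.log2_ratio, hg.log2_ratio)
    return CategoryAssignment(
        gene_id="", category=category, call_parents=p.value,
        call_hybrid_paternal=hb.value, call_hybrid_maternal=hg.value,
        chi_paternal=chi_paternal, chi_maternal=chi_maternal, at_elv=at_elv,
    )


def _statistical_calls(gene_id: str, de_results: Mapping[str, Mapping[str, str]]
                       ) -> tuple[str, str, str]:
    """Derive (P, Hb, Hg) from three pre-computed DE contrasts.

    ``de_results`` maps contrast names ``parents`` (paternal vs maternal),
    ``hybrid_paternal`` and ``hybrid_maternal`` (hybrid vs that parent) to
    per-gene calls in {"up", "down", "ns"}.
    """
    translate = {"up": "higher", "down": "lower", "ns": "equal"}
    try:
        return tuple(
            translate[de_results[contrast][gene_id]]
            for contrast in ("parents", "hybrid_paternal", "hybrid_maternal")
        )  # type: ignore[return-value]
    except KeyError as exc:
        raise ValueError(f"statistical mode: missing call for gene {gene_id!r} "
                         f"({exc})") from None


def classify_all(expr: Sequence[GroupExpression] | pd.DataFrame,
                 config: ClassifierConfig | None = None,
                 de_results: Mapping[str, Mapping[str, str]] | None = None
                 ) -> tuple[list[CategoryAssignment], dict]:
    """Classify every gene; returns (assignments, summary).

    Order of precedence per gene: Silenced, Novel, Excluded (any remaining
    zero group mean), then the twelve-category decision table.  In
    statistical mode ``de_results`` must carry all three contrasts (see
    :func:`_statistical_calls`); inconsistent call triples surface as
    Unresolved.
    """
    config = config or ClassifierConfig()
    if isinstance(expr, pd.DataFrame):
        expr = [
            GroupExpression(gene_id=str(g), chi_paternal=row.chi_paternal,
                            chi_maternal=row.chi_maternal, at_elv=row.at_elv)
            for g, row in expr.iterrows()
        ]
    if config.mode == "statistical" and de_results is None:
        raise ValueError("statistical mode requires de_results for all three contrasts")

    assignments: list[CategoryAssignment] = []
    for e in expr:
        if detect_silenced(e.chi_paternal, e.chi_maternal, e.at_elv, config):
            cat = Category.SILENCED
        elif detect_novel(e.chi_paternal, e.chi_maternal, e.at_elv, config):
            cat = Category.NOVEL
        elif e.chi_paternal == 0 or e.chi_maternal == 0 or e.at_elv == 0:
            cat = Category.EXCLUDED
        else:
            if config.mode == "statistical":
                p, hb, hg = _statistical_calls(e.gene_id, de_results)  # type: ignore[arg-type]
                a = CategoryAssignment(gene_id=e.gene_id, category=_decide(p, hb, hg),
                                       call_parents=p, call_hybrid_paternal=hb,
                                       call_hybrid_maternal=hg,
                                       chi_paternal=e.chi_paternal,
                                       chi_maternal=e.chi_maternal, at_elv=e.at_elv)
                assignments.append(a)
                continue
            a = classify_gene(e.chi_paternal, e.chi_maternal, e.at_elv, config)
            a.gene_id = e.gene_id
            assignments.append(a)
            continue
        assignments.append(CategoryAssignment(
            gene_id=e.gene_id, category=cat, chi_paternal=e.chi_paternal,
            chi_maternal=e.chi_maternal, at_elv=e.at_elv))
    return assignments, summarize(assignments)


def summarize(assignments: Iterable[CategoryAssignment]) -> dict:
    """Per-category counts plus the five standard groupings."""
    counts: dict[str, int] = {c.value: 0 for c in Category}
    for a in assignments:
        counts[a.category.value] += 1
    summary = dict(counts)
    for name, members in GROUPINGS.items():
        summary[name] = sum(counts[c.value] for c in members)
    summary["n_genes"] = sum(counts.values())
    summary["n_classified"] = sum(counts[c.value] for c in ROMAN) + counts["NoChange"] \
        + counts["Ambiguous"] + counts["Unresolved"]
    return summary
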