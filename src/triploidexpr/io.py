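"""Domain containers and tab-separated readers/writers.

The pipeline's entry point is a gene × sample matrix of integer read
counts together with per-gene transcript lengths (bp) and a sample → group
map.  Groups are fixed to the roles ``paternal`` / ``maternal`` / ``hybrid``
rather than species names so that any parent/hybrid trio can be analysed.

Also houses the bundled growth-gene reference panel: 45 liver-expressed
growth-pathway genes from a grass carp (maternal) × blunt snout bream
(paternal) triploid hybrid, with published per-genotype mean RPKM and
expression-category labels.  It serves as a ground-truth fixture for the
expression-category classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

PATERNAL = "paternal"
MATERNAL = "maternal"
HYBRID = "hybrid"
GROUPS = (PATERNAL, MATERNAL, HYBRID)


@dataclass(frozen=True)
class GeneRecord:
    """One gene/transcript: identifier, length L (bp) and optional symbol."""

    gene_id: str
    length_bp: int
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )


@dataclass(frozen=True)
class GroupExpression:
    """Per-gene mean RPKM of the three genotype groups.

    ``chi_paternal`` and ``chi_maternal`` are the parental means; ``at_elv``
    is the actual triploid (hybrid) expression level.
    """

    gene_id: str
    chi_paternal: float
    chi_maternal: float
    at_elv: float

    def __post_init__(self) -> None:
        for name in ("chi_paternal", "chi_maternal", "at_elv"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"gene {self.gene_id!r}: {name} must be finite and >= 0, got {v}")


@dataclass
class ExpressionMatrix:
    """Gene × sample integer read counts with lengths and group roles.

    ``library_size`` holds the per-sample total mapped reads N used for
    RPKM; it defaults to the column sum of ``counts`` (floored at 1) when
    not supplied.
    """

    genes: list[GeneRecord]
    samples: list[str]
    group_of: dict[str, str]
    counts: np.ndarray
    library_size: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.genes[g].gene_id!r}, sample {self.samples[s]!r}"
            )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id(s): {dupes}")
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValueError(f"sample(s) missing from group map: {missing}")
        bad = {s: g for s, g in self.group_of.items() if s in self.samples and g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group label(s) (expected one of {GROUPS}): {bad}")
        for grp in GROUPS:
            if not self.samples_in(grp):
                raise ValueError(f"group {grp!r} has no samples")
        if self.library_size is None:
            self.library_size = np.maximum(self.counts.sum(axis=0), 1).astype(np.int64)
        else:
            self.library_size = np.asarray(self.library_size, dtype=np.int64)
            if self.library_size.shape != (len(self.samples),):
                raise ValueError("library_size must have one entry per sample")
            if (self.library_size < 1).any():
                raise ValueError("library_size must be >= 1 for every sample")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.length_bp for g in self.genes], dtype=np.int64)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of.get(s) == group]

    def column_indices(self, group: str) -> list[int]:
        return [self.samples.index(s) for s in self.samples_in(group)]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a sample → group map from two-column TSV or YAML."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: YAML group map must be a mapping of sample: group")
        return {str(k): str(v) for k, v in mapping.items()}
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            if parts[0] in ("sample", "sample_id") and parts[1] in ("group", "role"):
                continue  # optional header
            mapping[parts[0]] = parts[1]
    return mapping


def read_count_matrix(path: str | Path, groups: Mapping[str, str] | str | Path,
                      library_size: Mapping[str, int] | None = None) -> ExpressionMatrix:
    """Read a count matrix TSV: ``gene_id<TAB>length_bp<TAB><sample...>``.

    ``groups`` may be an in-memory mapping or a path to a group-map file.
    ``library_size`` optionally overrides the default per-sample column sums.
    """
    path = Path(path)
    if not isinstance(groups, Mapping):
        groups = read_group_map(groups)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "gene_id" or header[1] != "length_bp":
            raise ValueError(
                f"{path}:1: header must start with 'gene_id<TAB>length_bp' followed by sample names"
            )
        samples = header[2:]
        genes: list[GeneRecord] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            gene_id = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer length_bp {parts[1]!r}") from None
            row = []
            for sample, cell in zip(samples, parts[2:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"(gene {gene_id!r}, sample {sample!r})"
                    ) from None
                if value < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative count {value} "
                        f"(gene {gene_id!r}, sample {sample!r})"
                    )
                row.append(value)
            try:
                genes.append(GeneRecord(gene_id, length))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rows.append(row)
    seen: set[str] = set()
    for lineno_offset, g in enumerate(genes):
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r} (line {lineno_offset + 2})")
        seen.add(g.gene_id)
    lib = None
    if library_size is not None:
        missing = [s for s in samples if s not in library_size]
        if missing:
            raise ValueError(f"library_size override missing sample(s): {missing}")
        lib = np.array([library_size[s] for s in samples], dtype=np.int64)
    return ExpressionMatrix(
        genes=genes,
        samples=samples,
        group_of={s: groups[s] for s in samples if s in groups},
        counts=np.array(rows, dtype=np.int64),
        library_size=lib,
    )


def write_count_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV format accepted by :func:`read_count_matrix`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_bp\t" + "\t".join(matrix.samples) + "\n")
        for g, row in zip(matrix.genes, matrix.counts):
            fh.write(g.gene_id + "\t" + str(g.length_bp) + "\t" +
                     "\t".join(str(int(c)) for c in row) + "\n")


def write_group_map(group_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in group_of.items():
            fh.write(f"{sample}\t{group}\n")


def read_library_sizes(path: str | Path) -> dict[str, int]:
    """Read a per-sample library-size override: two-column TSV sample<TAB>N."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            if parts[0] in ("sample", "sample_id"):
                continue
            try:
                n = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer library size "
                                 f"{parts[1]!r}") from None
            if n < 1:
                raise ValueError(f"{path}:{lineno}: library size must be >= 1")
            sizes[parts[0]] = n
    return sizes


def write_library_sizes(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlibrary_size\n")
        for sample, n in zip(matrix.samples, matrix.library_size):
            fh.write(f"{sample}\t{int(n)}\n")


# -- bundled growth-gene reference panel --------------------------------------

def load_growth_panel() -> pd.DataFrame:
    """Load the bundled 45-gene growth panel.

    Columns: ``symbol``, ``protein_id``, ``rpkm_paternal`` (blunt snout
    bream), ``rpkm_hybrid`` (triploid), ``rpkm_maternal`` (grass carp) and
    the published ``category`` label (Roman numeral I–XII).  Values are
    stored exactly as published (two decimals); they are not re-derived
    from counts.
    """
    with resources.files("triploidexpr.data").joinpath("growth_genes_rpkm.tsv").open() as fh:
        panel = pd.read_csv(fh, sep="\t", dtype={"symbol": str, "category": str})
    if len(panel) != 45:
        raise RuntimeError(f"growth panel corrupted: expected 45 rows, found {len(panel)}")
    return panel


def growth_panel_expression() -> list[GroupExpression]:
    """The growth panel as per-gene group means (symbol used as gene_id)."""
    panel = load_growth_panel()
    return [
        GroupExpression(
            gene_id=row.symbol,
            chi_paternal=row.rpkm_paternal,
            chi_maternal=row.rpkm_maternal,
            at_elv=row.rpkm_hybrid,
        )
        for row in panel.itertuples()
    ]


# -- classifier-result serialisation ------------------------------------------

RESULT_COLUMNS = [
    "gene_id", "chi_paternal", "chi_maternal", "at_elv",
    "call_parents", "call_hybrid_paternal", "call_hybrid_maternal", "category",
]


def write_results(assignments: Sequence, path: str | Path,
                  summary: Mapping[str, int] | None = None) -> Path:
    """Write category assignments as TSV plus a JSON per-category summary.

    ``assignments`` are :class:`~triploidexpr.classifier.CategoryAssignment`
    records.  The JSON summary is written next to the TSV with a
    ``.summary.json`` suffix; when ``summary`` is not given it is recomputed
    from the assignments.
    """
    if not assignments:
        raise ValueError("write_results: empty assignment list")
    path = Path(path)
    rows = []
    for a in assignments:
        rows.append({
            "gene_id": a.gene_id,
            "chi_paternal": a.chi_paternal,
            "chi_maternal": a.chi_maternal,
            "at_elv": a.at_elv,
            "call_parents": a.call_parents or "",
            "call_hybrid_paternal": a.call_hybrid_paternal or "",
            "call_hybrid_maternal": a.call_hybrid_maternal or "",
            "category": str(a.category),
        })
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    if summary is None:
        summary = {}
        for a in assignments:
            key = str(a.category)
            summary[key] = summary.get(key, 0) + 1
    summary_path = path.with_suffix(path.suffix + ".summary.json") \
        if path.suffix != ".tsv" else path.with_name(path.stem + ".summary.json")
    with open(summary_path, "w") as fh:
        json.dump(dict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary_path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a :func:`write_results` TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "category": str},
                        keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: not a results table, missing column(s) {missing}")
    return frame
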