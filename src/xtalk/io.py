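"""Data model and file I/O.

The pipeline exchanges plain tab-separated text: a genes x samples count
matrix per tissue, a sample sheet describing the cross-sectional design, a
GMT gene-set collection (with optional process-category and expected-direction
annotations carried in the description field), and a per-animal phenotype
table. All readers validate their contracts and raise the named errors from
:mod:`xtalk.errors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateGeneError,
    EmptyGeneSetError,
    GmtFormatError,
    NegativeCountError,
    NonIntegerCountError,
    SampleMismatchError,
    SampleSheetError,
)

TISSUES = ("liver", "aorta")
DIETS = ("chow", "HFD")
CATEGORIES = ("lipid", "inflammation", "fibrosis", "other")

SHEET_COLUMNS = ["sample_id", "animal_id", "tissue", "diet", "time_weeks"]


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Design metadata: one row per sample (tissue x animal)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise SampleSheetError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise SampleSheetError(f"duplicate sample ids: {dup}")
        bad_tissue = set(df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise SampleSheetError(f"unknown tissues: {sorted(bad_tissue)}")
        bad_diet = set(df["diet"]) - set(DIETS)
        if bad_diet:
            raise SampleSheetError(f"unknown diets: {sorted(bad_diet)}")
        t = pd.to_numeric(df["time_weeks"], errors="coerce")
        if t.isna().any() or (t <= 0).any() or (t != t.astype(int)).any():
            raise SampleSheetError("time_weeks must be positive integers")
        object.__setattr__(self, "frame", df.assign(time_weeks=t.astype(int)))

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.frame["time_weeks"].unique().tolist())

    def samples(
        self,
        tissue: str | None = None,
        diet: str | None = None,
        time_weeks: int | None = None,
    ) -> list[str]:
        df = self.frame
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if diet is not None:
            df = df[df["diet"] == diet]
        if time_weeks is not None:
            df = df[df["time_weeks"] == time_weeks]
        return df["sample_id"].tolist()

    def write(self, path: str | Path) -> None:
        self.frame[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "animal_id": str}))


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples integer counts (index: gene ids, columns: sample ids)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise DuplicateGeneError(f"duplicate gene ids: {dup}")
        values = df.to_numpy()
        if np.issubdtype(values.dtype, np.floating):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise NonIntegerCountError("count matrix contains non-integer entries")
            df = df.astype(np.int64)
        elif not np.issubdtype(values.dtype, np.integer):
            raise NonIntegerCountError(
                f"count matrix has non-numeric dtype {values.dtype}"
            )
        if (df.to_numpy() < 0).any():
            raise NegativeCountError("count matrix contains negative entries")
        object.__setattr__(self, "frame", df)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def write(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def read_count_matrix(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a genes-in-rows counts TSV and validate it against the sheet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    cm = CountMatrix(df)
    extra = set(cm.sample_ids) - set(sheet.frame["sample_id"])
    if extra:
        raise SampleMismatchError(
            f"samples absent from the sample sheet: {sorted(extra)}"
        )
    return cm


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str = "other"
    genes: frozenset[str] = frozenset()
    expected_direction: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise EmptyGeneSetError(f"gene set {self.name!r} has no genes")
        if self.category not in CATEGORIES:
            raise GmtFormatError(
                f"gene set {self.name!r}: unknown category {self.category!r}"
            )
        stray = set(self.expected_direction) - set(self.genes)
        if stray:
            raise GmtFormatError(
                f"gene set {self.name!r}: expected_direction keys not in set: {sorted(stray)}"
            )
        if any(v not in (-1, 1) for v in self.expected_direction.values()):
            raise GmtFormatError(f"gene set {self.name!r}: directions must be +/-1")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise GmtFormatError("gene set names are not unique")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def by_name(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def by_category(self, *categories: str) -> "GeneSetCollection":
        return GeneSetCollection(
            tuple(s for s in self.sets if s.category in categories)
        )

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= set(s.genes)
        return out

    def sets_containing(self, gene: str) -> list[str]:
        return [s.name for s in self.sets if gene in s.genes]


def _parse_gmt_description(desc: str) -> tuple[str, dict[str, int]]:
    """Parse ``category=... dir:GENE=+1 ...`` tokens from a GMT description."""
    category = "other"
    directions: dict[str, int] = {}
    for token in desc.split():
        if token.startswith("category="):
            category = token.split("=", 1)[1]
        elif token.startswith("dir:"):
            body = token[4:]
            if "=" not in body:
                raise GmtFormatError(f"malformed direction token {token!r}")
            gene, value = body.split("=", 1)
            try:
                directions[gene] = int(value)
            except ValueError as exc:
                raise GmtFormatError(f"malformed direction token {token!r}") from exc
    return category, directions


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise GmtFormatError(f"{path}:{lineno}: expected name and description")
        name, desc = fields[0], fields[1]
        genes = [g for g in fields[2:] if g]
        if not genes:
            raise EmptyGeneSetError(f"{path}:{lineno}: gene set {name!r} has no genes")
        category, directions = _parse_gmt_description(desc)
        directions = {g: d for g, d in directions.items() if g in set(genes)}
        sets.append(
            GeneSet(
                name=name,
                category=category,
                genes=frozenset(genes),
                expected_direction=directions,
            )
        )
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for s in collection:
        desc = f"category={s.category}"
        for gene in sorted(s.expected_direction):
            desc += f" dir:{gene}={s.expected_direction[gene]:+d}"
        lines.append("\t".join([s.name, desc] + sorted(s.genes)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "animal_id",
    "diet",
    "time_weeks",
    "body_weight",
    "glucose",
    "insulin",
    "steatosis",
    "inflammation",
    "fibrosis",
    "lesion_area",
]

_PERCENT_COLUMNS = ("steatosis", "fibrosis")


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-animal metabolic and histological measurements.

    Units follow the study conventions: body weight g, glucose mM, insulin
    ng/mL, steatosis and fibrosis as % area, inflammation as aggregates/mm2,
    lesion area in arbitrary area units.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise SampleSheetError(f"phenotype table missing columns: {missing}")
        numeric = PHENOTYPE_COLUMNS[3:]
        if (df[list(numeric)].to_numpy() < 0).any():
            raise SampleSheetError("phenotype values must be >= 0")
        for col in _PERCENT_COLUMNS:
            if (df[col] > 100).any():
                raise SampleSheetError(f"{col} is a percentage and must be <= 100")

    def write(self, path: str | Path) -> None:
        self.frame[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PhenotypeTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls(pd.read_csv(path, sep="\t", dtype={"animal_id": str}))
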