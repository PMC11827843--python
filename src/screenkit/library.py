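"""sgRNA library designs, sample sheets and count tables.

A pooled knockout screen is described by three tab-delimited artifacts:

* a **library annotation** mapping each guide to its gene and category
  (``target`` gene of interest, ``essential`` positive control, ``ntc``
  non-targeting negative control);
* a **sample sheet** listing the sequenced samples and their arm
  (``T0`` baseline, ``vehicle``, or ``drug``);
* a **count table** of integer read counts, one row per guide and one
  column per sample.

NTC guides carry their own guide id as a placeholder gene label: each NTC
guide is an independent unit until the resampling stage aggregates them
into pseudogenes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError, InvalidParameterError

__all__ = [
    "CATEGORIES",
    "GuideRecord",
    "LibraryDesign",
    "SampleEntry",
    "SampleSheet",
    "CountTable",
    "Violation",
    "compose_library",
    "read_library",
    "write_library",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_count_table",
    "write_count_table",
    "validate_screen",
]

GUIDE_COL = "GUIDE"
GENE_COL = "GENE"
CATEGORY_COL = "CATEGORY"
ANNOTATION_COLS = (GUIDE_COL, GENE_COL, CATEGORY_COL)

CATEGORIES = ("target", "essential", "ntc")
ARMS = ("T0", "vehicle", "drug")


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: unique id, gene symbol (or NTC placeholder), category."""

    guide_id: str
    gene: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidParameterError(
                f"category {self.category!r} not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class LibraryDesign:
    """An ordered sgRNA library with per-category tallies.

    Invariants enforced at construction: unique guide ids, one category per
    gene, and (for composed libraries) ``guides_per_gene`` guides for every
    target/essential gene.
    """

    guides: tuple[GuideRecord, ...]
    guides_per_gene: int = 4

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        dup = [k for k, v in Counter(ids).items() if v > 1]
        if dup:
            raise ConsistencyError(f"duplicate guide ids in library: {dup[:5]}")
        gene_cat: dict[str, str] = {}
        for g in self.guides:
            prev = gene_cat.setdefault(g.gene, g.category)
            if prev != g.category:
                raise ConsistencyError(
                    f"gene {g.gene!r} carries mixed categories {prev!r}/{g.category!r}"
                )

    @property
    def guide_ids(self) -> tuple[str, ...]:
        return tuple(g.guide_id for g in self.guides)

    @property
    def category_counts(self) -> dict[str, int]:
        return dict(Counter(g.category for g in self.guides))

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    def genes(self, category: str | None = None) -> tuple[str, ...]:
        """Gene labels, in library order, optionally restricted to a category."""
        seen: dict[str, None] = {}
        for g in self.guides:
            if category is None or g.category == category:
                seen.setdefault(g.gene)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                GUIDE_COL: [g.guide_id for g in self.guides],
                GENE_COL: [g.gene for g in self.guides],
                CATEGORY_COL: [g.category for g in self.guides],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, guides_per_gene: int = 4) -> "LibraryDesign":
        guides = tuple(
            GuideRecord(str(r[GUIDE_COL]), str(r[GENE_COL]), str(r[CATEGORY_COL]))
            for r in frame.to_dict("records")
        )
        return cls(guides=guides, guides_per_gene=guides_per_gene)


def compose_library(
    n_target_genes: int,
    n_essential_genes: int,
    n_ntc_guides: int,
    guides_per_gene: int = 4,
) -> LibraryDesign:
    """Compose a synthetic library with a deterministic naming scheme.

    Target genes are named ``TGT0001``..., essentials ``ESS0001``..., and
    their guides ``<gene>_g<k>``.  NTC guides are ``NTC_0001``... and each
    uses its own id as gene label.

    >>> d = compose_library(356, 63, 324, 4)
    >>> d.n_guides
    2000
    """
    for name, v in (
        ("n_target_genes", n_target_genes),
        ("n_essential_genes", n_essential_genes),
        ("n_ntc_guides", n_ntc_guides),
    ):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {v}")
    if guides_per_gene < 1:
        raise InvalidParameterError(f"guides_per_gene must be >= 1, got {guides_per_gene}")

    guides: list[GuideRecord] = []
    for prefix, n, category in (
        ("TGT", n_target_genes, "target"),
        ("ESS", n_essential_genes, "essential"),
    ):
        for i in range(1, n + 1):
            gene = f"{prefix}{i:04d}"
            for k in range(1, guides_per_gene + 1):
                guides.append(GuideRecord(f"{gene}_g{k}", gene, category))
    for i in range(1, n_ntc_guides + 1):
        gid = f"NTC_{i:04d}"
        guides.append(GuideRecord(gid, gid, "ntc"))
    return LibraryDesign(guides=tuple(guides), guides_per_gene=guides_per_gene)


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    arm: str
    cell_line: str
    drug_name: str | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidParameterError(f"arm {self.arm!r} not in {ARMS}")
        if (self.arm == "drug") != (self.drug_name is not None):
            raise InvalidParameterError(
                f"sample {self.sample_id!r}: drug_name must be present iff arm='drug'"
            )
        if self.replicate < 1:
            raise InvalidParameterError("replicate must be >= 1")


@dataclass(frozen=True)
class SampleSheet:
    entries: tuple[SampleEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        dup = [k for k, v in Counter(ids).items() if v > 1]
        if dup:
            raise ConsistencyError(f"duplicate sample ids: {dup}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(e.sample_id for e in self.entries)

    def entry(self, sample_id: str) -> SampleEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)


@dataclass
class CountTable:
    """Guide annotation joined with an integer count matrix.

    ``data`` holds the columns ``GUIDE``, ``GENE``, ``CATEGORY`` followed by
    one integer column per sample, in sample-sheet order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLS if c not in self.data.columns]
        if missing:
            raise FormatError(f"count table missing annotation columns {missing}")
        self.data = self.data.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.data.columns if c not in ANNOTATION_COLS]

    @property
    def n_guides(self) -> int:
        return len(self.data)

    def counts(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        return self.data[list(samples) if samples is not None else self.samples]

    def subset(self, mask) -> "CountTable":
        return CountTable(self.data.loc[mask].reset_index(drop=True))

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy())


def write_library(design: LibraryDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_library(path: str | Path, guides_per_gene: int = 4) -> LibraryDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLS if c not in frame.columns]
    if missing:
        raise FormatError(f"library annotation missing columns {missing}")
    bad = sorted(set(frame[CATEGORY_COL]) - set(CATEGORIES))
    if bad:
        raise FormatError(f"unknown categories {bad}; expected one of {CATEGORIES}")
    return LibraryDesign.from_frame(frame, guides_per_gene=guides_per_gene)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    rows = [
        {
            "SAMPLE": e.sample_id,
            "ARM": e.arm,
            "CELL_LINE": e.cell_line,
            "DRUG": e.drug_name if e.drug_name is not None else "-",
            "REPLICATE": e.replicate,
        }
        for e in sheet.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["SAMPLE", "ARM", "CELL_LINE", "DRUG", "REPLICATE"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    entries = tuple(
        SampleEntry(
            sample_id=r["SAMPLE"],
            arm=r["ARM"],
            cell_line=r["CELL_LINE"],
            drug_name=None if r["DRUG"] in ("-", "", None) else r["DRUG"],
            replicate=int(r["REPLICATE"]),
        )
        for r in frame.to_dict("records")
    )
    return SampleSheet(entries=entries)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write ``GUIDE<TAB>GENE<TAB><samples...>`` (category lives in the library)."""
    cols = [GUIDE_COL, GENE_COL] + table.samples
    table.data[cols].to_csv(path, sep="\t", index=False)


def read_count_table(
    path: str | Path,
    library: LibraryDesign,
    samples: SampleSheet | None = None,
) -> CountTable:
    """Read and validate a tab-delimited count table against a library.

    Row order is preserved; sample columns are coerced to nonnegative
    integers.  Raises :class:`FormatError` on a missing mandatory column,
    ``ValueError`` on non-integer or negative counts, and
    :class:`ConsistencyError` for guides absent from the library.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in (GUIDE_COL, GENE_COL):
        if col not in frame.columns:
            raise FormatError(f"count table missing mandatory column {col!r}")
    sample_cols = [c for c in frame.columns if c not in (GUIDE_COL, GENE_COL, CATEGORY_COL)]
    if not sample_cols:
        raise FormatError("count table has no sample columns")
    for col in sample_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            raise ValueError(f"non-numeric count in column {col!r}")
        if (numeric % 1 != 0).any():
            raise ValueError(f"non-integer count in column {col!r}")
        if (numeric < 0).any():
            raise ValueError(f"negative count in column {col!r}")
        frame[col] = numeric.astype("int64")

    known = {g.guide_id: g for g in library.guides}
    unknown = [g for g in frame[GUIDE_COL] if g not in known]
    if unknown:
        raise ConsistencyError(f"guides absent from library: {unknown[:5]}")
    frame[CATEGORY_COL] = [known[g].category for g in frame[GUIDE_COL]]
    table = CountTable(frame[[GUIDE_COL, GENE_COL, CATEGORY_COL] + sample_cols])
    if samples is not None:
        violations = [v for v in validate_screen(table, samples) if v.kind == "unknown-sample"]
        if violations:
            warnings.warn("; ".join(v.message for v in violations), stacklevel=2)
    return table


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str


def validate_screen(table: CountTable, samples: SampleSheet) -> list[Violation]:
    """Screen-level sanity checks; violations are reported, never raised.

    Flags duplicate guide rows, sample columns absent from the sheet,
    sheet samples absent from the table, genes with mixed categories,
    and guides whose counts are zero in every sample (flagged, kept).
    """
    out: list[Violation] = []
    dup = table.data[GUIDE_COL][table.data[GUIDE_COL].duplicated()].unique()
    for g in dup:
        out.append(Violation("duplicate-guide", f"guide {g!r} appears more than once"))
    sheet_ids = set(samples.sample_ids)
    for col in table.samples:
        if col not in sheet_ids:
            out.append(Violation("unknown-sample", f"column {col!r} not in sample sheet"))
    for sid in samples.sample_ids:
        if sid not in table.samples:
            out.append(Violation("missing-sample", f"sheet sample {sid!r} absent from table"))
    cats = table.data.groupby(GENE_COL)[CATEGORY_COL].nunique()
    for gene in cats[cats > 1].index:
        out.append(Violation("category-conflict", f"gene {gene!r} has mixed categories"))
    if table.samples:
        zero = table.data.loc[(table.counts().sum(axis=1) == 0), GUIDE_COL]
        for g in zero:
            out.append(Violation("all-zero-guide", f"guide {g!r} has zero counts in all samples"))
    return out
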