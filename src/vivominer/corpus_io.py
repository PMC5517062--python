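"""Loading and summarizing the assay, compound and assay-compound link tables.

The corpus is a delimited text table of curated whole-organism bioassays: one
row per assay with an identifier, the free-text description, the species (rat
or mouse), the identifier of the source publication, and the identifiers of
the compounds tested. Compound rows carry name, WHO ATC classification codes
and the maximum development phase reached (4 = approved drug). Column names
and delimiter are config-driven (supplementary spreadsheets vs TSV exports),
and the assay-compound join is a separate two-column mapping table because the
relation is many-to-many.
"""

from __future__ import annotations

import json
import logging
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssayRecord",
    "CompoundRecord",
    "CorpusStats",
    "TableDialect",
    "LoadReport",
    "load_assay_table",
    "load_compound_table",
    "load_link_table",
    "corpus_stats",
    "default_tokenizer",
]

SPECIES = ("rat", "mouse")
ATC_CODE_RE = re.compile(r"^[A-Z]\d{2}(?:[A-Z]{1,2}(?:\d{2})?)?$")


@dataclass(frozen=True)
class AssayRecord:
    assay_id: str
    description: str
    species: str
    document_id: str
    compound_ids: tuple[str, ...] = ()

    def validate(self) -> str | None:
        """Reason string if an invariant is violated, else None."""
        if not self.description.strip():
            return "empty_description"
        if self.species not in SPECIES:
            return "invalid_species"
        if not self.document_id.strip():
            return "empty_document_id"
        return None


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    atc_codes: tuple[str, ...] = ()
    max_phase: int = 0


@dataclass
class CorpusStats:
    n_assays: int
    n_per_species: dict[str, int]
    n_documents: int
    n_distinct_compounds: int
    n_assays_with_approved_drug: int
    desc_length_mean: float
    desc_length_median: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TableDialect:
    """Column mapping and delimiter for a delimited text table."""

    sep: str = "\t"
    columns: dict[str, str] = field(default_factory=dict)  # canonical -> file column

    def col(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass
class LoadReport:
    path: str
    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def _read_table(path: str | Path, dialect: TableDialect, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if dialect.col(c) not in df.columns]
    if missing:
        raise KeyError(
            f"{path}: missing required column(s) {missing} "
            f"(available: {list(df.columns)})"
        )
    return df


def load_assay_table(
    path: str | Path, dialect: TableDialect | None = None
) -> tuple[list[AssayRecord], LoadReport]:
    """Load assays; rows violating record invariants are dropped and counted."""
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect, ["assay_id", "description", "species", "document_id"])
    report = LoadReport(str(path), n_read=len(df))
    records: list[AssayRecord] = []
    has_compounds = dialect.col("compound_ids") in df.columns
    for row in df.to_dict("records"):
        get = lambda c: str(row.get(dialect.col(c), "")).strip()  # noqa: E731
        compound_ids = tuple(
            c.strip() for c in get("compound_ids").split("|") if c.strip()
        ) if has_compounds else ()
        rec = AssayRecord(
            assay_id=get("assay_id"),
            description=get("description"),
            species=get("species").lower(),
            document_id=get("document_id"),
            compound_ids=compound_ids,
        )
        reason = rec.validate()
        if reason is None:
            records.append(rec)
            report.n_kept += 1
        else:
            report.dropped[reason] = report.dropped.get(reason, 0) + 1
    return records, report


def load_compound_table(
    path: str | Path, dialect: TableDialect | None = None
) -> tuple[list[CompoundRecord], LoadReport]:
    """Load compounds. ATC codes are upper-cased and validated; a malformed
    code is dropped with a warning while the record is kept. Records with no
    ATC code are retained (novel-compound accounting needs them)."""
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect, ["compound_id"])
    report = LoadReport(str(path), n_read=len(df))
    records = []
    for row in df.to_dict("records"):
        get = lambda c: str(row.get(dialect.col(c), "")).strip()  # noqa: E731
        codes = []
        for raw in get("atc_codes").split("|"):
            raw = raw.strip().upper()
            if not raw:
                continue
            if ATC_CODE_RE.match(raw):
                codes.append(raw)
            else:
                msg = f"compound {get('compound_id')}: malformed ATC code {raw!r} dropped"
                report.warnings.append(msg)
                logger.warning(msg)
        try:
            max_phase = int(float(get("max_phase") or 0))
        except ValueError:
            max_phase = 0
        records.append(
            CompoundRecord(get("compound_id"), get("name"), tuple(codes),
                           min(max(max_phase, 0), 4))
        )
        report.n_kept += 1
    return records, report


def load_link_table(
    path: str | Path, dialect: TableDialect | None = None
) -> tuple[list[tuple[str, str]], LoadReport]:
    """Load the (assay_id, compound_id) many-to-many mapping."""
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect, ["assay_id", "compound_id"])
    report = LoadReport(str(path), n_read=len(df), n_kept=len(df))
    pairs = [
        (str(a).strip(), str(c).strip())
        for a, c in zip(df[dialect.col("assay_id")], df[dialect.col("compound_id")])
    ]
    return pairs, report


_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:[^\s]*[A-Za-z0-9])?")


def default_tokenizer(text: str) -> list[str]:
    """Whitespace words after stripping leading/trailing punctuation — the
    word-counting rule behind the description length statistics."""
    return _WORD_RE.findall(text)


def corpus_stats(
    assays: Sequence[AssayRecord],
    compounds: Sequence[CompoundRecord] = (),
    links: Iterable[tuple[str, str]] | None = None,
    tokenizer: Callable[[str], list[str]] = default_tokenizer,
    normalize: Callable[[str], str] | None = None,
) -> CorpusStats:
    """Corpus-level summary. ``normalize`` optionally pre-transforms each
    description before word counting (e.g. acronym expansion), since either
    convention is defensible for length statistics."""
    if not assays:
        return CorpusStats(0, {s: 0 for s in SPECIES}, 0, 0, 0, 0.0, 0.0)
    lengths = [
        len(tokenizer(normalize(a.description) if normalize else a.description))
        for a in assays
    ]
    per_species = {s: sum(a.species == s for a in assays) for s in SPECIES}

    approved = {c.compound_id for c in compounds if c.max_phase == 4}
    assay_compounds: dict[str, set[str]] = {a.assay_id: set(a.compound_ids) for a in assays}
    if links is not None:
        for aid, cid in links:
            if aid in assay_compounds:
                assay_compounds[aid].add(cid)
    n_approved = sum(bool(cids & approved) for cids in assay_compounds.values())
    distinct_compounds = set().union(*assay_compounds.values()) if assay_compounds else set()
    return CorpusStats(
        n_assays=len(assays),
        n_per_species=per_species,
        n_documents=len({a.document_id for a in assays}),
        n_distinct_compounds=len(distinct_compounds),
        n_assays_with_approved_drug=n_approved,
        desc_length_mean=float(statistics.mean(lengths)),
        desc_length_median=float(statistics.median(lengths)),
    )


def write_assay_table(assays: Sequence[AssayRecord], path: str | Path) -> None:
    """Normalized TSV snapshot (round-trips through load_assay_table)."""
    pd.DataFrame(
        [
            (a.assay_id, a.description, a.species, a.document_id, "|".join(a.compound_ids))
            for a in assays
        ],
        columns=["assay_id", "description", "species", "document_id", "compound_ids"],
    ).to_csv(path, sep="\t", index=False)
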