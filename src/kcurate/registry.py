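"""Curated gene-catalog data model and the packaged gene-table fixture.

The registry is a validated table of curated channel-family genes: gene
models, orthology class, dN/dS versus chicken, allelic-variant letter
codes, and per-nucleus expression scores.  A companion fixture lists the
human genes with no counterpart in the curated genome, partitioned into
loss categories.  Counting and reconciliation operations over the two
fixtures reproduce the headline totals of the survey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Union

from .expression import ExpressionProfile

SUBFAMILIES = frozenset(
    {
        "KCNA", "KCNAB", "KCNB", "KCNF", "KCNG", "KCNS", "KCNV", "KCNC",
        "KCND", "KCNIP", "KCNH", "KCNE", "KCNQ", "KCNMA", "KCNMB", "KCNN",
        "KCNT", "KCNJ", "KCNK", "HCN", "KCTD",
    }
)
MODEL_STATUSES = frozenset({"complete", "partial", "none"})
ORTHOLOG_CLASSES = frozenset({"one_to_one_human", "novel_non_human", "pseudogene"})
NOVELTY_FLAGS = frozenset({"none", "delta", "hash", "dollar"})
VARIANT_CODES = frozenset({"S", "C", "NC", "I", "D"})
MISSING_CATEGORIES = (
    "human_pseudogene",
    "missing_in_finch",
    "missing_in_birds",
    "missing_in_sauropsids",
    "missing_in_tetrapods_or_mammal_specific",
)

#: dN/dS qualifier tokens stored verbatim instead of as floats.
DNDS_QUALIFIERS = frozenset({"lt_0_01", "not_available"})

COLUMNS = (
    "symbol", "subfamily", "model_ids", "model_status", "ortholog_class",
    "novelty_flag", "chicken_ortholog", "dnds", "dnds_note", "dnds_flagged",
    "variant_codes", "hvc", "lman", "ra", "x", "clone",
)


class RegistryError(ValueError):
    """Malformed registry input (bad cell, duplicate symbol, bad header)."""


@dataclass(frozen=True)
class GeneRecord:
    """One curated gene with its annotations and expression profile."""

    symbol: str
    subfamily: str
    model_ids: tuple[str, ...]
    model_status: str
    ortholog_class: str
    novelty_flag: str
    chicken_ortholog: str  # identifier/locus text, or "none"
    dnds: Union[float, str]  # float, or a qualifier in DNDS_QUALIFIERS
    dnds_note: str  # opaque footnote numerals from the source table
    dnds_flagged: bool
    variant_codes: frozenset[str]
    expression: ExpressionProfile
    clone_id: str  # accession, or "no_clone" / "clone_untested:<acc>"

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise RegistryError(f"{self.symbol}: unknown subfamily {self.subfamily!r}")
        if self.model_status not in MODEL_STATUSES:
            raise RegistryError(f"{self.symbol}: bad model_status {self.model_status!r}")
        if self.ortholog_class not in ORTHOLOG_CLASSES:
            raise RegistryError(
                f"{self.symbol}: bad ortholog_class {self.ortholog_class!r}"
            )
        if self.novelty_flag not in NOVELTY_FLAGS:
            raise RegistryError(f"{self.symbol}: bad novelty_flag {self.novelty_flag!r}")
        if not self.variant_codes <= VARIANT_CODES:
            raise RegistryError(
                f"{self.symbol}: bad variant codes {sorted(self.variant_codes)}"
            )
        if isinstance(self.dnds, str) and self.dnds not in DNDS_QUALIFIERS:
            raise RegistryError(f"{self.symbol}: bad dnds value {self.dnds!r}")
        if isinstance(self.dnds, float) and (self.dnds < 0 or math.isnan(self.dnds)):
            raise RegistryError(f"{self.symbol}: dnds must be non-negative")
        if self.dnds_flagged and not (
            isinstance(self.dnds, float) and self.dnds > 0.1
        ):
            raise RegistryError(
                f"{self.symbol}: dnds_flagged requires a numeric dN/dS > 0.1"
            )
        if (self.ortholog_class == "novel_non_human") != (self.novelty_flag == "delta"):
            raise RegistryError(
                f"{self.symbol}: novel_non_human class and delta flag must co-occur"
            )

    def dnds_numeric(self, coerce_qualifiers: bool = False) -> float | None:
        """Numeric dN/dS; qualifiers map to None unless coercion is asked.

        With ``coerce_qualifiers`` the below-detection qualifier becomes
        0.005; "not available" stays None either way.
        """
        if isinstance(self.dnds, float):
            return self.dnds
        if self.dnds == "lt_0_01" and coerce_qualifiers:
            return 0.005
        return None


@dataclass(frozen=True)
class MissingGeneRecord:
    """A human gene with no ortholog evidence in the curated genome."""

    symbol: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in MISSING_CATEGORIES:
            raise RegistryError(f"{self.symbol}: bad category {self.category!r}")


class Registry:
    """Ordered collection of GeneRecords with unique symbols."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._records = list(records)
        seen: set[str] = set()
        for rec in self._records:
            if rec.symbol in seen:
                raise RegistryError(f"duplicate symbol {rec.symbol!r}")
            seen.add(rec.symbol)
        self._by_symbol = {r.symbol: r for r in self._records}

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self._by_symbol[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def symbols(self) -> list[str]:
        return [r.symbol for r in self._records]

    def without(self, symbol: str) -> "Registry":
        return Registry(r for r in self._records if r.symbol != symbol)


def _parse_clone(token: str) -> str:
    token = token.strip()
    if token in ("No clone", ""):
        return "no_clone"
    if token.endswith("†"):
        return f"clone_untested:{token[:-1].strip()}"
    return token


def _parse_dnds(token: str) -> Union[float, str]:
    token = token.strip()
    if token in DNDS_QUALIFIERS:
        return token
    try:
        return float(token)
    except ValueError:
        raise RegistryError(f"unparseable dN/dS cell {token!r}") from None


def _parse_bool(token: str) -> bool:
    if token == "true":
        return True
    if token == "false":
        return False
    raise RegistryError(f"expected true/false, got {token!r}")


def _split_list(token: str) -> tuple[str, ...]:
    token = token.strip()
    if not token:
        return ()
    return tuple(part.strip() for part in token.split(","))


def _record_from_row(row: dict[str, str], lineno: int) -> GeneRecord:
    try:
        expression = ExpressionProfile.from_tokens(
            {n: row[n] for n in ("hvc", "lman", "ra", "x")}
        )
        return GeneRecord(
            symbol=row["symbol"].strip(),
            subfamily=row["subfamily"].strip(),
            model_ids=_split_list(row["model_ids"]),
            model_status=row["model_status"].strip(),
            ortholog_class=row["ortholog_class"].strip(),
            novelty_flag=row["novelty_flag"].strip(),
            chicken_ortholog=row["chicken_ortholog"].strip(),
            dnds=_parse_dnds(row["dnds"]),
            dnds_note=row["dnds_note"].strip(),
            dnds_flagged=_parse_bool(row["dnds_flagged"].strip()),
            variant_codes=frozenset(_split_list(row["variant_codes"])),
            expression=expression,
            clone_id=_parse_clone(row["clone"]),
        )
    except ValueError as exc:
        raise RegistryError(f"row {lineno}: {exc}") from exc


def default_registry_path() -> Path:
    return Path(resources.files("kcurate").joinpath("data/gene_table.tsv"))  # type: ignore[arg-type]


def default_missing_path() -> Path:
    return Path(resources.files("kcurate").joinpath("data/missing_genes.tsv"))  # type: ignore[arg-type]


def load_registry(path: str | Path | None = None) -> Registry:
    """Load the registry TSV; default is the packaged gene-table fixture."""
    path = Path(path) if path is not None else default_registry_path()
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise RegistryError(f"{path}: empty file, header required")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != COLUMNS:
        raise RegistryError(
            f"{path}: header mismatch; expected {COLUMNS}, got {header}"
        )
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(COLUMNS):
            raise RegistryError(
                f"{path}: row {lineno} has {len(cells)} cells, expected {len(COLUMNS)}"
            )
        records.append(_record_from_row(dict(zip(COLUMNS, cells)), lineno))
    return Registry(records)


def serialize_registry(registry: Registry) -> str:
    """Render a registry back to the TSV dialect (column order fixed)."""
    out = ["\t".join(COLUMNS)]
    for rec in registry:
        cells = _row_cells(rec)
        out.append("\t".join(cells))
    return "\n".join(out) + "\n"


def _format_expression(rec: GeneRecord) -> dict[str, str]:
    prof = rec.expression
    if prof.status == "not_determined":
        return {n: "N.D." for n in ("hvc", "lman", "ra", "x")}
    if prof.status == "no_signal":
        return {n: "NS" for n in ("hvc", "lman", "ra", "x")}
    levels = {0: "o", 1: "+", 2: "++", 3: "+++"}
    arrows = {1: "↑", 2: "↑↑", -1: "↓", -2: "↓↓"}
    cells = {}
    for n, (lvl, direction) in prof.cells.items():
        text = levels[lvl]
        if direction:
            text += f" ({arrows[direction]})"
        cells[n] = text
    return cells


def _row_cells(rec: GeneRecord) -> list[str]:
    if isinstance(rec.dnds, float):
        dnds = f"{rec.dnds:.2f}"
    else:
        dnds = rec.dnds
    if rec.clone_id == "no_clone":
        clone = "No clone"
    elif rec.clone_id.startswith("clone_untested:"):
        clone = rec.clone_id.split(":", 1)[1] + "†"
    else:
        clone = rec.clone_id
    expr = _format_expression(rec)
    codes = sorted(rec.variant_codes, key=lambda c: ("S", "C", "NC", "I", "D").index(c))
    return [
        rec.symbol,
        rec.subfamily,
        ",".join(rec.model_ids),
        rec.model_status,
        rec.ortholog_class,
        rec.novelty_flag,
        rec.chicken_ortholog,
        dnds,
        rec.dnds_note,
        "true" if rec.dnds_flagged else "false",
        ",".join(codes),
        expr["hvc"],
        expr["lman"],
        expr["ra"],
        expr["x"],
        clone,
    ]


def load_missing_genes(path: str | Path | None = None) -> list[MissingGeneRecord]:
    path = Path(path) if path is not None else default_missing_path()
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["symbol", "category"]:
        raise RegistryError(f"{path}: expected header 'symbol<TAB>category'")
    records = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        symbol, _, category = line.partition("\t")
        if symbol in seen:
            raise RegistryError(f"{path}: duplicate symbol {symbol!r} at row {lineno}")
        seen.add(symbol)
        records.append(MissingGeneRecord(symbol=symbol, category=category.strip()))
    return records


# ---------------------------------------------------------------------------
# Declarative predicates


@dataclass(frozen=True)
class Predicate:
    """Declarative filter: (field, relation, value).

    Relations: eq, ne, gt, ge, lt, le, contains (set/tuple membership),
    intersects (non-empty set intersection).  Numeric relations on the
    ``dnds`` field skip qualifier-valued records unless ``coerce_dnds``.
    """

    field: str
    relation: str
    value: object
    coerce_dnds: bool = False

    def __call__(self, rec: GeneRecord) -> bool:
        if not hasattr(rec, self.field) and self.field != "dnds":
            raise RegistryError(f"unknown field {self.field!r}")
        actual = getattr(rec, self.field)
        if self.field == "dnds" and self.relation in ("gt", "ge", "lt", "le"):
            actual = rec.dnds_numeric(coerce_qualifiers=self.coerce_dnds)
            if actual is None:
                return False
        ops: dict[str, Callable[[object, object], bool]] = {
            "eq": lambda a, b: a == b,
            "ne": lambda a, b: a != b,
            "gt": lambda a, b: a > b,
            "ge": lambda a, b: a >= b,
            "lt": lambda a, b: a < b,
            "le": lambda a, b: a <= b,
            "contains": lambda a, b: b in a,
            "intersects": lambda a, b: bool(frozenset(a) & frozenset(b)),
        }
        if self.relation not in ops:
            raise RegistryError(f"unknown relation {self.relation!r}")
        return ops[self.relation](actual, self.value)


@dataclass(frozen=True)
class And:
    parts: tuple

    def __call__(self, rec: GeneRecord) -> bool:
        return all(p(rec) for p in self.parts)


@dataclass(frozen=True)
class Or:
    parts: tuple

    def __call__(self, rec: GeneRecord) -> bool:
        return any(p(rec) for p in self.parts)


FALSE = Or(parts=())
TRUE = And(parts=())


def count_by_predicate(registry: Registry, predicate) -> int:
    """Number of records satisfying a declarative predicate."""
    return sum(1 for rec in registry if predicate(rec))


def filter_by_predicate(registry: Registry, predicate) -> list[GeneRecord]:
    return [rec for rec in registry if predicate(rec)]


# ---------------------------------------------------------------------------
# Reconciliation


def reconcile_annotations(
    registry: Registry, missing: list[MissingGeneRecord]
) -> dict:
    """Reconcile the curated registry against the missing-gene list.

    The human starting set equals the 1-to-1 orthologs plus every human
    gene without curated-genome evidence; the curated total equals the
    1-to-1 orthologs plus the novel non-human genes.  Violated identities
    are listed in the report rather than raised.
    """
    one_to_one = count_by_predicate(
        registry, Predicate("ortholog_class", "eq", "one_to_one_human")
    )
    novel = count_by_predicate(
        registry, Predicate("ortholog_class", "eq", "novel_non_human")
    )
    pseudo = count_by_predicate(
        registry, Predicate("ortholog_class", "eq", "pseudogene")
    )
    finch_total = len(registry)
    missing_total = len(missing)
    by_category = {c: 0 for c in MISSING_CATEGORIES}
    for rec in missing:
        by_category[rec.category] += 1
    human_start = one_to_one + missing_total
    violations = []
    if finch_total != one_to_one + novel + pseudo:
        violations.append(
            f"finch_total {finch_total} != one_to_one {one_to_one} + "
            f"novel {novel} + pseudogene {pseudo}"
        )
    if sum(by_category.values()) != missing_total:
        violations.append("missing categories do not partition the missing set")
    return {
        "finch_total": finch_total,
        "one_to_one": one_to_one,
        "novel_non_human": novel,
        "pseudogene": pseudo,
        "missing_total": missing_total,
        "missing_by_category": by_category,
        "human_start": human_start,
        "violations": violations,
    }


__all__ = [
    "GeneRecord", "MissingGeneRecord", "Registry", "RegistryError",
    "Predicate", "And", "Or", "TRUE", "FALSE",
    "load_registry", "load_missing_genes", "serialize_registry",
    "count_by_predicate", "filter_by_predicate", "reconcile_annotations",
    "default_registry_path", "default_missing_path", "replace",
]
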