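"""CITES Trade Database parsing, filtering and source-class adjustment.

The CITES comparative tabulation reports one row per (year, exporter,
importer, term, purpose, source) combination with the quantities each
party reported. The audit keeps live-lion permits imported into lion
range states over 1983–2019 with purpose codes N (release to the wild),
T, B, H (commercial, breeding, trophy) and source codes W, F, R, C or
blank, then amalgamates them into four trade categories and re-examines
the source coding:

* F/R-coded exports come from managed wild stock → class W2;
* South African 'W' exports after 2005 are assumed to originate from the
  managed metapopulation (Kruger closed by bovine TB, Kgalagadi off-take
  rare) → W2;
* South African exports with a missing source code are wild (W1) before
  the mid-1990s (almost no captive facilities existed) and W2 after;
* an explicit, citable override table reclassifies individual flows
  (e.g. the Akagera restocking was permit-coded captive but sourced from
  the managed metapopulation).

Quantities are reconciled to the maximum of the importer- and
exporter-reported figures: permit quantities are intended maxima.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._countries import normalize_country

__all__ = [
    "TradeRecord",
    "TradeCategory",
    "AdjustedRecord",
    "Override",
    "ParseResult",
    "FilterResult",
    "CitesSchemaError",
    "ClassificationError",
    "read_cites_csv",
    "reconcile_quantity",
    "filter_records",
    "categorize_trade",
    "adjust_source",
    "adjust_records",
    "load_overrides",
    "write_adjusted",
]

YEAR_MIN_DEFAULT = 1983
YEAR_MAX_DEFAULT = 2019
#: "mid-1990s" cutoff for the missing-source heuristic on South African
#: exports: reserves date from 1991 and captive facilities were rare
#: pre-1994, so blank-source exports strictly before this year count as wild.
MID_NINETIES_CUTOFF = 1995

PURPOSE_KEEP = frozenset({"N", "T", "B", "H"})
SOURCE_KEEP = frozenset({"W", "F", "R", "C", ""})

_WILD_CODES = frozenset({"W", "F", "R"})


class CitesSchemaError(ValueError):
    """Input CSV does not look like a CITES comparative tabulation."""


class ClassificationError(ValueError):
    """Source/purpose codes outside the categorisation domain."""


class TradeCategory(enum.Enum):
    WILD_REINTRO = "wild (re)introduction"
    CAPTIVE_REINTRO = "captive (re)introduction"
    WILD_COMMERCIAL = "wild commercial/breeding/trophy"
    CAPTIVE_COMMERCIAL = "captive commercial/breeding/trophy"


@dataclass(frozen=True)
class TradeRecord:
    """One comparative-tabulation row after parsing."""

    year: int
    taxon: str
    importer: str
    exporter: str
    origin: str = ""
    qty_importer: float | None = None
    qty_exporter: float | None = None
    term: str = ""
    unit: str = ""
    purpose: str = ""
    source: str = ""
    line: int | None = None  # 1-based line number in the input file

    @property
    def source_country(self) -> str:
        """Country used for genetic attribution: origin when it names a
        different country than the exporter (the exporter may be a transit
        state), else the exporter."""
        if self.origin and self.origin != self.exporter:
            return self.origin
        return self.exporter


@dataclass(frozen=True)
class AdjustedRecord:
    """A trade record after reconciliation, categorisation and adjustment."""

    record: TradeRecord
    quantity: int
    source_class: str  # W1 | W2 | C | U
    category: TradeCategory | None
    adjustment_rule: str

    def __post_init__(self) -> None:
        if self.quantity < 1:
            raise ValueError("adjusted records carry at least one individual")
        if self.source_class not in {"W1", "W2", "C", "U"}:
            raise ValueError(f"bad source class {self.source_class!r}")


@dataclass(frozen=True)
class Override:
    """One row of the audit override table (auditable reclassification)."""

    exporter: str
    importer: str
    year_min: int
    year_max: int
    source_class: str
    citation: str = ""

    def matches(self, rec: TradeRecord) -> bool:
        return (
            rec.exporter == self.exporter
            and rec.importer == self.importer
            and self.year_min <= rec.year <= self.year_max
        )


@dataclass
class ParseResult:
    """Parsed records plus line-numbered diagnostics for malformed rows."""

    records: list[TradeRecord] = field(default_factory=list)
    problems: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterResult:
    """Kept records plus a per-filter exclusion tally.

    ``excluded[reason] = (n_records, n_individuals)``; individuals are the
    reconciled quantities, so input individuals = kept + sum(excluded).
    """

    kept: list[TradeRecord] = field(default_factory=list)
    excluded: dict[str, tuple[int, int]] = field(default_factory=dict)

    def individuals_kept(self) -> int:
        return sum(reconcile_quantity(r) for r in self.kept)

    def individuals_excluded(self) -> int:
        return sum(n for _, n in self.excluded.values())


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_COLUMN_SYNONYMS = {
    "year": "year",
    "taxon": "taxon",
    "importer": "importer",
    "exporter": "exporter",
    "origin": "origin",
    "importer reported quantity": "qty_importer",
    "importer-reported quantity": "qty_importer",
    "exporter reported quantity": "qty_exporter",
    "exporter-reported quantity": "qty_exporter",
    "term": "term",
    "unit": "unit",
    "purpose": "purpose",
    "source": "source",
}


def _parse_qty(cell: str) -> float | None:
    s = str(cell).strip()
    if not s:
        return None
    v = float(s)
    if v < 0:
        raise ValueError(f"negative quantity {s!r}")
    return v


def _is_lion(taxon: str) -> bool:
    return taxon.strip().lower().startswith("panthera leo")


def read_cites_csv(path: str | Path) -> ParseResult:
    """Parse a CITES comparative-tabulation CSV.

    Malformed rows (unparseable year or quantity, missing countries) are
    reported with their line numbers in ``ParseResult.problems``, never
    silently dropped. Raises :class:`CitesSchemaError` when the header does
    not contain the expected columns.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower().replace("_", " ")
        if key in _COLUMN_SYNONYMS:
            colmap[_COLUMN_SYNONYMS[key]] = col
    required = {"year", "taxon", "importer", "exporter", "term", "purpose", "source"}
    missing = required - set(colmap)
    has_qty = {"qty_importer", "qty_exporter"} & set(colmap)
    if missing or not has_qty:
        raise CitesSchemaError(
            f"unrecognised CITES header: found {list(df.columns)}, "
            f"missing {sorted(missing) or 'a quantity column'}"
        )

    result = ParseResult()
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            year_s = str(row[colmap["year"]]).strip()
            if not (year_s.isdigit() and len(year_s) == 4):
                raise ValueError(f"year {year_s!r} is not a 4-digit integer")
            rec = TradeRecord(
                year=int(year_s),
                taxon=str(row[colmap["taxon"]]).strip(),
                importer=normalize_country(row[colmap["importer"]], allow_pseudo=True),
                exporter=normalize_country(row[colmap["exporter"]], allow_pseudo=True),
                origin=(
                    normalize_country(row[colmap["origin"]], allow_pseudo=True)
                    if "origin" in colmap and str(row[colmap["origin"]]).strip()
                    else ""
                ),
                qty_importer=_parse_qty(row[colmap["qty_importer"]]) if "qty_importer" in colmap else None,
                qty_exporter=_parse_qty(row[colmap["qty_exporter"]]) if "qty_exporter" in colmap else None,
                term=str(row[colmap["term"]]).strip().lower(),
                unit=str(row[colmap["unit"]]).strip() if "unit" in colmap else "",
                purpose=str(row[colmap["purpose"]]).strip().upper(),
                source=str(row[colmap["source"]]).strip().upper(),
                line=line,
            )
            result.records.append(rec)
        except (ValueError, KeyError) as exc:
            result.problems.append(f"line {line}: {exc}")
    return result


# ---------------------------------------------------------------------------
# Quantity reconciliation and filtering
# ---------------------------------------------------------------------------


def reconcile_quantity(record: TradeRecord, rule: str = "max") -> int:
    """Reconcile importer/exporter quantities to a single individual count.

    ``max`` (default) keeps the permit-intended maximum; ``exporter``
    prefers the exporter-reported figure when present. Returns 0 when both
    quantities are missing or zero (the record is then excluded).
    """
    qi = record.qty_importer or 0.0
    qe = record.qty_exporter or 0.0
    if rule == "max":
        q = max(qi, qe)
    elif rule == "exporter":
        q = qe if qe > 0 else qi
    else:
        raise ValueError(f"unknown quantity rule {rule!r}")
    return int(math.ceil(q - 1e-9)) if q > 0 else 0


def filter_records(
    records: Iterable[TradeRecord],
    range_states: frozenset[str] | set[str],
    year_min: int = YEAR_MIN_DEFAULT,
    year_max: int = YEAR_MAX_DEFAULT,
    quantity_rule: str = "max",
) -> FilterResult:
    """Apply the audit inclusion filters with a per-filter exclusion tally.

    Keeps live lions, 1983–2019, imported into a lion range state, purpose
    in {N, T, B, H}, source in {W, F, R, C, blank}, positive quantity.
    Exclusions are data, not errors: the tally conserves individuals.
    """
    out = FilterResult()

    def exclude(reason: str, rec: TradeRecord) -> None:
        n, q = out.excluded.get(reason, (0, 0))
        out.excluded[reason] = (n + 1, q + reconcile_quantity(rec, quantity_rule))

    for rec in records:
        if not _is_lion(rec.taxon):
            exclude("taxon-not-lion", rec)
        elif rec.term != "live":
            exclude("term-not-live", rec)
        elif not (year_min <= rec.year <= year_max):
            exclude("year-out-of-range", rec)
        elif rec.importer not in range_states:
            exclude("importer-not-range-state", rec)
        elif rec.purpose not in PURPOSE_KEEP:
            exclude("purpose-excluded", rec)
        elif rec.source not in SOURCE_KEEP:
            exclude("source-excluded", rec)
        elif reconcile_quantity(rec, quantity_rule) < 1:
            exclude("zero-quantity", rec)
        else:
            out.kept.append(rec)
    return out


# ---------------------------------------------------------------------------
# Categorisation and source-class adjustment
# ---------------------------------------------------------------------------


def categorize_trade(source_class_raw: str, purpose: str) -> TradeCategory:
    """Map raw (source, purpose) codes onto the four consolidated categories."""
    src = source_class_raw.strip().upper()
    pur = purpose.strip().upper()
    if src not in _WILD_CODES | {"C"} or pur not in PURPOSE_KEEP:
        raise ClassificationError(f"codes outside domain: source={src!r} purpose={pur!r}")
    wild = src in _WILD_CODES
    reintro = pur == "N"
    if wild and reintro:
        return TradeCategory.WILD_REINTRO
    if not wild and reintro:
        return TradeCategory.CAPTIVE_REINTRO
    if wild:
        return TradeCategory.WILD_COMMERCIAL
    return TradeCategory.CAPTIVE_COMMERCIAL


def adjust_source(
    record: TradeRecord,
    overrides: Sequence[Override] = (),
    *,
    mid_nineties_cutoff: int = MID_NINETIES_CUTOFF,
    fr_w2_all_exporters: bool = True,
    quantity_rule: str = "max",
) -> AdjustedRecord:
    """Assign the adjusted source class (W1/W2/C/U) to a filtered record.

    Clause precedence (first match wins):

    1. explicit override table entry;
    2. source F or R → W2 (managed wild stock);
    3. South African 'W' export after 2005 → W2;
    4. South African blank source before the mid-1990s cutoff → W1;
    5. South African blank source from the cutoff on → W2;
    6. source W → W1;
    7. source C → C;
    8. otherwise → U (unknown).
    """
    src = record.source
    cls: str
    rule: str
    matched = next((o for o in overrides if o.matches(record)), None)
    if matched is not None:
        cls, rule = matched.source_class, f"override ({matched.citation or 'table'})"
    elif src in {"F", "R"} and (fr_w2_all_exporters or record.exporter == "ZA"):
        cls, rule = "W2", "F/R source code -> managed wild stock"
    elif record.exporter == "ZA" and src == "W" and record.year > 2005:
        cls, rule = "W2", "ZA 'W' post-2005 -> managed metapopulation"
    elif record.exporter == "ZA" and src == "" and record.year < mid_nineties_cutoff:
        cls, rule = "W1", f"ZA missing source pre-{mid_nineties_cutoff} -> wild"
    elif record.exporter == "ZA" and src == "":
        cls, rule = "W2", f"ZA missing source {mid_nineties_cutoff}+ -> managed metapopulation"
    elif src == "W":
        cls, rule = "W1", "source code W -> wild"
    elif src == "C":
        cls, rule = "C", "source code C -> captive"
    else:
        cls, rule = "U", "no source information"

    if src in _WILD_CODES | {"C"} and record.purpose in PURPOSE_KEEP:
        category: TradeCategory | None = categorize_trade(src, record.purpose)
    elif record.purpose in PURPOSE_KEEP and cls in {"W1", "W2"}:
        # blank raw source inferred wild: categorise by the adjusted class
        category = TradeCategory.WILD_REINTRO if record.purpose == "N" else TradeCategory.WILD_COMMERCIAL
    else:
        category = None
    return AdjustedRecord(
        record=record,
        quantity=reconcile_quantity(record, quantity_rule),
        source_class=cls,
        category=category,
        adjustment_rule=rule,
    )


def adjust_records(
    records: Iterable[TradeRecord], overrides: Sequence[Override] = (), **kwargs
) -> list[AdjustedRecord]:
    return [adjust_source(r, overrides, **kwargs) for r in records]


def load_overrides(path: str | Path) -> list[Override]:
    """Load the override table (columns: exporter, importer, year_min,
    year_max, source_class, citation)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"exporter", "importer", "year_min", "year_max", "source_class"}
    missing = required - set(df.columns)
    if missing:
        raise CitesSchemaError(f"override table missing column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            Override(
                exporter=normalize_country(row["exporter"], allow_pseudo=True),
                importer=normalize_country(row["importer"], allow_pseudo=True),
                year_min=int(row["year_min"]),
                year_max=int(row["year_max"]),
                source_class=str(row["source_class"]).strip().upper(),
                citation=str(row.get("citation", "")).strip(),
            )
        )
    return out


def write_adjusted(adjusted: Sequence[AdjustedRecord], path: str | Path) -> Path:
    """Write adjusted records as CSV (CITES columns + audit columns)."""
    rows = []
    for a in adjusted:
        r = a.record
        rows.append(
            {
                "Year": r.year,
                "Taxon": r.taxon,
                "Importer": r.importer,
                "Exporter": r.exporter,
                "Origin": r.origin,
                "Importer reported quantity": "" if r.qty_importer is None else r.qty_importer,
                "Exporter reported quantity": "" if r.qty_exporter is None else r.qty_exporter,
                "Term": r.term,
                "Unit": r.unit,
                "Purpose": r.purpose,
                "Source": r.source,
                "quantity": a.quantity,
                "source_class": a.source_class,
                "category": a.category.name if a.category else "",
                "adjustment_rule": a.adjustment_rule,
            }
        )
    out = Path(path)
    pd.DataFrame(rows).to_csv(out, index=False, encoding="utf-8")
    return out
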