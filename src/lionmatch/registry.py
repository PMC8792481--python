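"""Clade-annotated registry of lion conservation units (LCUs).

Each registry row describes one managed lion population: the countries it
spans, its mitochondrial and nuclear clade assignment(s), how certain that
assignment is, and management flags (natural suture zone, human-mediated
hybrid origin, membership of the South African managed metapopulation).
The registry is the genetic reference against which translocation
source/target pairs and CITES trade records are scored.

File format: UTF-8 delimited text (comma by default, tab accepted) with
columns ``id, name, countries, mtdna, nudna, certainty, suture_zone,
hybrid_origin, managed_metapopulation, extant, notes``. Multi-valued cells
(countries, clade labels) use ``|`` as the separator.
"""

from __future__ import annotations

import importlib.resources
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from ._countries import ISO_ALPHA2, normalize_country

__all__ = [
    "CladeVocabulary",
    "GeneticProfile",
    "LCURecord",
    "Registry",
    "CountryProfile",
    "RegistryError",
    "SchemaError",
    "EmptyRegistryError",
    "NoPopulationError",
    "load_registry",
    "write_registry",
    "country_profile",
    "default_registry",
    "default_range_states",
    "load_config",
    "SUTURE_ZONE_COUNTRIES",
]

CERTAINTY_LEVELS = ("high", "fairly_high", "medium")
SUTURE_ZONES = ("SZ1", "SZ2")

#: Countries the two natural suture zones span: SZ1 = Sudan, South Sudan,
#: Ethiopia (the *P. l. leo* / *P. l. melanochaita* contact zone); SZ2 =
#: Zambia, Malawi, Mozambique.
SUTURE_ZONE_COUNTRIES: dict[str, frozenset[str]] = {
    "SZ1": frozenset({"SD", "SS", "ET"}),
    "SZ2": frozenset({"ZM", "MW", "MZ"}),
}

REGISTRY_COLUMNS = (
    "id",
    "name",
    "countries",
    "mtdna",
    "nudna",
    "certainty",
    "suture_zone",
    "hybrid_origin",
    "managed_metapopulation",
    "extant",
    "notes",
)


class RegistryError(ValueError):
    """Invalid registry content."""


class SchemaError(RegistryError):
    """Registry file does not match the documented schema."""


class EmptyRegistryError(RegistryError):
    """Registry file contains no data rows."""


class NoPopulationError(RegistryError):
    """Country has no extant population in the registry."""


def _norm_label(label: str) -> str:
    """Case-normalise a clade label (title-case words, keep '/' groupings)."""
    parts = label.strip().replace("_", " ").split()
    return " ".join(p if p.isupper() and len(p) <= 3 else p.title() for p in parts)


@dataclass(frozen=True)
class CladeVocabulary:
    """The clade label inventory and the nuclear-clade → subspecies map.

    The default vocabulary follows the continent-wide lion phylogeography:
    six mtDNA haplogroups and five nuclear clades, with the West, Central
    and India nuclear clades belonging to *P. l. leo* and the East and
    Southern clades to *P. l. melanochaita*.
    """

    mtdna_labels: frozenset[str]
    nudna_labels: frozenset[str]
    subspecies_of: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = self.nudna_labels - set(self.subspecies_of)
        if missing:
            raise RegistryError(
                f"nuDNA labels without a subspecies mapping: {sorted(missing)}"
            )

    @classmethod
    def default(cls) -> "CladeVocabulary":
        return cls(
            mtdna_labels=frozenset(
                {"West", "Central", "North East", "East/Southern", "South West", "India"}
            ),
            nudna_labels=frozenset({"West", "Central", "East", "Southern", "India"}),
            subspecies_of={
                "West": "leo",
                "Central": "leo",
                "India": "leo",
                "East": "melanochaita",
                "Southern": "melanochaita",
            },
        )

    def normalize_mt(self, label: str) -> str:
        out = _norm_label(label)
        if out not in self.mtdna_labels:
            raise RegistryError(f"unknown mtDNA clade label: {label!r}")
        return out

    def normalize_nu(self, label: str) -> str:
        out = _norm_label(label)
        if out not in self.nudna_labels:
            raise RegistryError(f"unknown nuDNA clade label: {label!r}")
        return out

    def subspecies(self, nu_label: str) -> str:
        return self.subspecies_of[nu_label]


@dataclass(frozen=True)
class GeneticProfile:
    """mtDNA and nuDNA clade assignment of a population.

    Multiple mtDNA labels encode natural haplogroup overlap (e.g. the KAZA
    landscape carries both East/Southern and South West haplotypes);
    multiple nuDNA labels encode suture zones where nuclear clades meet.
    """

    mtdna: frozenset[str]
    nudna: frozenset[str]

    def __post_init__(self) -> None:
        if not self.mtdna or not self.nudna:
            raise RegistryError("profile requires at least one mtDNA and one nuDNA label")

    def validate(self, vocabulary: CladeVocabulary) -> None:
        bad_mt = self.mtdna - vocabulary.mtdna_labels
        bad_nu = self.nudna - vocabulary.nudna_labels
        if bad_mt or bad_nu:
            raise RegistryError(
                f"labels outside vocabulary: mt={sorted(bad_mt)} nu={sorted(bad_nu)}"
            )

    def subspecies(self, vocabulary: CladeVocabulary) -> frozenset[str]:
        return frozenset(vocabulary.subspecies(n) for n in self.nudna)


@dataclass(frozen=True)
class LCURecord:
    """One lion conservation unit (registry row)."""

    id: str
    name: str
    countries: frozenset[str]
    profile: GeneticProfile
    certainty: str = "high"
    suture_zone: str | None = None
    hybrid_origin: bool = False
    managed_metapopulation: bool = False
    extant: bool = True
    notes: str = ""

    def validate(self, vocabulary: CladeVocabulary) -> None:
        self.profile.validate(vocabulary)
        if self.certainty not in CERTAINTY_LEVELS:
            raise RegistryError(
                f"record {self.id}: certainty must be one of {CERTAINTY_LEVELS}"
            )
        if self.suture_zone is not None:
            if self.suture_zone not in SUTURE_ZONES:
                raise RegistryError(
                    f"record {self.id}: suture_zone must be one of {SUTURE_ZONES}"
                )
            in_sz_countries = bool(
                self.countries & SUTURE_ZONE_COUNTRIES.get(self.suture_zone, frozenset())
            )
            if len(self.profile.nudna) < 2 and not in_sz_countries:
                raise RegistryError(
                    f"record {self.id}: suture-zone record needs >=2 nuDNA labels "
                    "or a country inside the suture zone"
                )
        bad = {c for c in self.countries if c not in ISO_ALPHA2}
        if bad:
            raise RegistryError(f"record {self.id}: invalid country codes {sorted(bad)}")
        if not self.countries:
            raise RegistryError(f"record {self.id}: at least one country required")


@dataclass
class Registry:
    """A validated collection of LCU records plus the active vocabulary."""

    vocabulary: CladeVocabulary
    records: list[LCURecord] = field(default_factory=list)
    range_states: frozenset[str] = frozenset()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise RegistryError(f"duplicate record id: {rec.id}")
            seen.add(rec.id)
            rec.validate(self.vocabulary)
        bad = {c for c in self.range_states if c not in ISO_ALPHA2}
        if bad:
            raise RegistryError(f"invalid range-state codes: {sorted(bad)}")
        covered = set()
        for rec in self.records:
            covered |= rec.countries
        uncovered = self.range_states - covered
        if uncovered:
            warnings.warn(
                f"range states without any registry record: {sorted(uncovered)}",
                stacklevel=2,
            )

    def by_id(self, record_id: str) -> LCURecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def records_for_country(self, country: str, *, extant_only: bool = True) -> list[LCURecord]:
        code = normalize_country(country)
        return [
            r
            for r in self.records
            if code in r.countries and (r.extant or not extant_only)
        ]


@dataclass(frozen=True)
class CountryProfile:
    """Union genetic profile of a country's extant LCUs, with aggregate flags."""

    country: str
    profile: GeneticProfile
    any_hybrid: bool
    any_suture: bool
    multi_clade: bool
    lcu_ids: tuple[str, ...]


def country_profile(registry: Registry, country: str) -> CountryProfile:
    """Union of the extant LCU profiles of ``country`` plus aggregate flags.

    ``multi_clade`` is set when the union spans more than one nuDNA clade —
    the situation where a CITES record naming only a country leaves the
    genetic assignment ambiguous.
    """
    code = normalize_country(country)
    recs = registry.records_for_country(code)
    if not recs:
        raise NoPopulationError(f"no extant population recorded for {code}")
    mt: frozenset[str] = frozenset()
    nu: frozenset[str] = frozenset()
    for r in recs:
        mt |= r.profile.mtdna
        nu |= r.profile.nudna
    return CountryProfile(
        country=code,
        profile=GeneticProfile(mtdna=mt, nudna=nu),
        any_hybrid=any(r.hybrid_origin for r in recs),
        any_suture=any(r.suture_zone for r in recs),
        multi_clade=len(nu) > 1,
        lcu_ids=tuple(sorted(r.id for r in recs)),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value: str, *, row: int, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY or v == "nan":
        return False
    raise RegistryError(f"row {row}: column {column!r} has non-boolean value {value!r}")


def _split_multi(cell: str) -> list[str]:
    return [p.strip() for p in str(cell).split("|") if p.strip()]


def _read_table(path: str | Path | io.StringIO) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, sep=None, engine="python", keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def load_registry(
    path: str | Path | io.StringIO,
    vocabulary: CladeVocabulary | None = None,
    range_states: Iterable[str] | None = None,
) -> Registry:
    """Load and validate a registry table (CSV or TSV).

    Rows with unknown clade labels, malformed country codes or duplicate ids
    are rejected with row-numbered diagnostics collected into a single
    :class:`RegistryError`.
    """
    vocabulary = vocabulary or CladeVocabulary.default()
    df = _read_table(path)
    required = set(REGISTRY_COLUMNS) - {"notes"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"registry file missing required column(s): {sorted(missing)}")
    if df.empty:
        raise EmptyRegistryError("registry file contains no data rows")

    records: list[LCURecord] = []
    problems: list[str] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            rec_id = str(row["id"]).strip()
            if not rec_id:
                raise RegistryError("empty id")
            if rec_id in seen_ids:
                raise RegistryError(f"duplicate id {rec_id!r}")
            countries = frozenset(
                normalize_country(c) for c in _split_multi(row["countries"])
            )
            profile = GeneticProfile(
                mtdna=frozenset(vocabulary.normalize_mt(m) for m in _split_multi(row["mtdna"])),
                nudna=frozenset(vocabulary.normalize_nu(n) for n in _split_multi(row["nudna"])),
            )
            sz = str(row["suture_zone"]).strip() or None
            if sz is not None and sz.lower() in {"none", "nan"}:
                sz = None
            rec = LCURecord(
                id=rec_id,
                name=str(row["name"]).strip(),
                countries=countries,
                profile=profile,
                certainty=str(row["certainty"]).strip().lower().replace(" ", "_"),
                suture_zone=sz.upper() if sz else None,
                hybrid_origin=_parse_bool(row["hybrid_origin"], row=rownum, column="hybrid_origin"),
                managed_metapopulation=_parse_bool(
                    row["managed_metapopulation"], row=rownum, column="managed_metapopulation"
                ),
                extant=_parse_bool(row["extant"], row=rownum, column="extant") if str(row["extant"]).strip() != "" else True,
                notes=str(row.get("notes", "")).strip(),
            )
            rec.validate(vocabulary)
            seen_ids.add(rec_id)
            records.append(rec)
        except (RegistryError, ValueError) as exc:
            problems.append(f"row {rownum}: {exc}")
    if problems:
        raise RegistryError("invalid registry rows:\n  " + "\n  ".join(problems))

    if range_states is None:
        states = frozenset().union(*(r.countries for r in records))
    else:
        states = frozenset(normalize_country(c) for c in range_states)
    reg = Registry(vocabulary=vocabulary, records=records, range_states=states)
    reg.validate()
    return reg


def write_registry(registry: Registry, path: str | Path) -> Path:
    """Write a registry as UTF-8 CSV; round-trips through :func:`load_registry`."""
    rows = []
    for r in registry.records:
        rows.append(
            {
                "id": r.id,
                "name": r.name,
                "countries": "|".join(sorted(r.countries)),
                "mtdna": "|".join(sorted(r.profile.mtdna)),
                "nudna": "|".join(sorted(r.profile.nudna)),
                "certainty": r.certainty,
                "suture_zone": r.suture_zone or "",
                "hybrid_origin": str(r.hybrid_origin).lower(),
                "managed_metapopulation": str(r.managed_metapopulation).lower(),
                "extant": str(r.extant).lower(),
                "notes": r.notes,
            }
        )
    out = Path(path)
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(out, index=False, encoding="utf-8")
    return out


# ---------------------------------------------------------------------------
# Packaged default registry
# ---------------------------------------------------------------------------

#: Lion range states used by default (countries with current wild lions
#: plus India; Gabon's Batéké population is included).
DEFAULT_RANGE_STATES: frozenset[str] = frozenset(
    {
        "AO", "BJ", "BW", "BF", "CM", "CF", "TD", "CD", "ET", "GA", "IN",
        "KE", "MW", "MZ", "NA", "NE", "NG", "RW", "SN", "SO", "SS", "SD",
        "SZ", "TZ", "UG", "ZA", "ZM", "ZW",
    }
)


def default_range_states() -> frozenset[str]:
    return DEFAULT_RANGE_STATES


def default_registry() -> Registry:
    """Load the packaged country-level default registry.

    This is a *country-level approximation* of the full 132-LCU table: it
    encodes only clade facts stated at country resolution (suture zones,
    KAZA mtDNA overlap, known hybrid populations, the India clade) and is
    intended as a fallback when the full LCU table is not available.
    """
    ref = importlib.resources.files("lionmatch.data") / "default_registry.csv"
    with importlib.resources.as_file(ref) as p:
        return load_registry(p, CladeVocabulary.default(), DEFAULT_RANGE_STATES)


# ---------------------------------------------------------------------------
# Configuration overrides
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML config with optional vocabulary / range-state overrides.

    Recognised keys: ``mtdna_labels``, ``nudna_labels``, ``subspecies_of``,
    ``range_states``, plus trade-adjustment knobs consumed by
    :mod:`lionmatch.cites` (``mid_nineties_cutoff``, ``fr_w2_all_exporters``,
    ``quantity_rule``).
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise RegistryError("config file must contain a mapping")
    return cfg


def vocabulary_from_config(cfg: Mapping) -> CladeVocabulary:
    base = CladeVocabulary.default()
    mt = frozenset(_norm_label(x) for x in cfg.get("mtdna_labels", [])) or base.mtdna_labels
    nu = frozenset(_norm_label(x) for x in cfg.get("nudna_labels", [])) or base.nudna_labels
    sub = {_norm_label(k): v for k, v in cfg.get("subspecies_of", {}).items()} or dict(
        base.subspecies_of
    )
    return CladeVocabulary(mtdna_labels=mt, nudna_labels=nu, subspecies_of=sub)
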