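"""Join adjusted CITES records to registry clade profiles and report.

Each permitted movement is scored with the translocation decision tree:
captive-sourced and unknown-origin individuals are 'no option' outright
(their genetic background is unknown), managed-metapopulation (W2)
individuals form their own reporting category, and wild individuals are
scored from the clade profiles of the exporting (or origin) and importing
countries. Countries harbouring several clades make a record ambiguous;
the pipeline then carries a best case and a worst case over all candidate
population pairs and propagates the interval into the summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cites import AdjustedRecord, FilterResult, TradeCategory
from .registry import Registry, country_profile
from .suitability import SuitabilityLevel, SuitabilityScore, score as score_lcu_pair

__all__ = [
    "ScoredRecord",
    "ClassStat",
    "SuitabilitySummary",
    "FlowEdge",
    "UnresolvableTargetError",
    "score_record",
    "score_records",
    "summarize",
    "scenario_no_option_range",
    "flow_edges",
    "export_reports",
]

CLASS_ORDER = ("FIRST", "SECOND", "THIRD", "W2", "NO_OPTION")


class UnresolvableTargetError(ValueError):
    """Importer country has no population in the registry."""


@dataclass(frozen=True)
class ScoredRecord:
    """An adjusted trade record with its suitability interval."""

    adjusted: AdjustedRecord
    source_profile: object  # CountryProfile or the string "captive-unknown"
    target_profile: object
    best_score: SuitabilityScore
    worst_score: SuitabilityScore
    scoring_note: str = ""

    def __post_init__(self) -> None:
        if self.best_score.level < self.worst_score.level:
            raise ValueError("best score must be at least as good as worst score")
        if self.adjusted.source_class in {"C", "U"} and not self.scoring_note.startswith(
            "scenario"
        ):
            assert self.best_score.level == SuitabilityLevel.NO_OPTION

    @property
    def quantity(self) -> int:
        return self.adjusted.quantity

    def suitability_class(self, *, use: str = "best") -> str:
        """Reporting class: W2 is its own category outside the four levels."""
        if self.adjusted.source_class == "W2":
            return "W2"
        sc = self.best_score if use == "best" else self.worst_score
        return sc.level.name


def _no_option(reason: str, **flags) -> SuitabilityScore:
    return SuitabilityScore(level=SuitabilityLevel.NO_OPTION, rationale=reason, **flags)


def score_record(
    record: AdjustedRecord,
    registry: Registry,
    *,
    assume_country_clade_for_captive: bool = False,
) -> ScoredRecord:
    """Score one adjusted record against the registry.

    Wild (W1/W2) individuals are attributed to their origin-or-exporter
    country; the best/worst interval spans the cartesian product of that
    country's candidate populations against the importer's. Captive (C)
    and unknown (U) individuals are 'no option' unless the sensitivity
    scenario assumes the exporting country's clade even for captive stock.
    """
    importer = record.record.importer
    try:
        registry_has_importer = bool(registry.records_for_country(importer))
    except ValueError:
        registry_has_importer = False
    if not registry_has_importer:
        raise UnresolvableTargetError(
            f"importer {importer!r} has no population in the registry "
            f"(record line {record.record.line})"
        )

    cls = record.source_class
    scenario = assume_country_clade_for_captive and cls in {"C", "U"}
    w2 = cls == "W2"
    if cls in {"C", "U"} and not assume_country_clade_for_captive:
        why = (
            "captive-sourced individual of unknown genetic background"
            if cls == "C"
            else "unknown source"
        )
        sc = _no_option(why)
        return ScoredRecord(
            adjusted=record,
            source_profile="captive-unknown",
            target_profile="captive-unknown",
            best_score=sc,
            worst_score=sc,
            scoring_note=why,
        )

    src_country = record.record.source_country
    try:
        src_recs = registry.records_for_country(src_country)
    except ValueError:
        src_recs = []
    if not src_recs:
        why = f"{'scenario: ' if scenario else ''}no clade profile for source country {src_country!r}"
        sc = _no_option(why)
        return ScoredRecord(
            adjusted=record,
            source_profile="captive-unknown",
            target_profile=country_profile(registry, importer),
            best_score=sc,
            worst_score=sc,
            scoring_note=why,
        )
    tgt_recs = registry.records_for_country(importer)

    scored = [
        score_lcu_pair(s, t, registry.vocabulary) for s in src_recs for t in tgt_recs
    ]
    best = max(scored, key=lambda s: s.level)
    worst = min(scored, key=lambda s: s.level)
    if w2:
        # managed metapopulation: flagged as its own category and as a
        # hybrid source (mixed East/Southern + South West stock)
        best = replace(best, w2_source=True, hybrid_source=True)
        worst = replace(worst, w2_source=True, hybrid_source=True)
    note = "scenario: captive scored by country clade" if scenario else (
        f"{len(src_recs)}x{len(tgt_recs)} candidate population pairs"
    )
    return ScoredRecord(
        adjusted=record,
        source_profile=country_profile(registry, src_country),
        target_profile=country_profile(registry, importer),
        best_score=best,
        worst_score=worst,
        scoring_note=note,
    )


def score_records(
    records: Iterable[AdjustedRecord],
    registry: Registry,
    *,
    assume_country_clade_for_captive: bool = False,
) -> list[ScoredRecord]:
    return [
        score_record(r, registry, assume_country_clade_for_captive=assume_country_clade_for_captive)
        for r in records
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassStat:
    count: int
    percent: int  # rounded to whole percent for report parity
    fraction: float


@dataclass
class SuitabilitySummary:
    individuals_total: int
    by_class: dict[str, ClassStat]
    by_exporter: dict[str, tuple[int, float, dict[str, int]]]
    by_importer: dict[str, tuple[int, float, dict[str, int]]]
    by_trade_category: dict[str, int]


def _stat(count: int, total: int) -> ClassStat:
    frac = count / total if total else 0.0
    return ClassStat(count=count, percent=round(100 * frac), fraction=frac)


def _country_tally(
    scored: Sequence[ScoredRecord], key, total: int
) -> dict[str, tuple[int, float, dict[str, int]]]:
    counts: dict[str, int] = {}
    breakdown: dict[str, dict[str, int]] = {}
    for s in scored:
        c = key(s)
        q = s.quantity
        counts[c] = counts.get(c, 0) + q
        bd = breakdown.setdefault(c, {})
        cls = s.suitability_class()
        bd[cls] = bd.get(cls, 0) + q
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        c: (n, (n / total if total else 0.0), dict(sorted(breakdown[c].items())))
        for c, n in ordered
    }


def summarize(scored: Sequence[ScoredRecord]) -> SuitabilitySummary:
    """Quantity-weighted tallies per class, country and trade category.

    W2 individuals are counted as their own class, parallel to the four
    suitability levels; class counts sum to the total by construction.
    """
    total = sum(s.quantity for s in scored)
    class_counts = {c: 0 for c in CLASS_ORDER}
    for s in scored:
        class_counts[s.suitability_class()] += s.quantity
    cat_counts: dict[str, int] = {}
    for s in scored:
        name = s.adjusted.category.name if s.adjusted.category else "UNCATEGORISED"
        cat_counts[name] = cat_counts.get(name, 0) + s.quantity
    return SuitabilitySummary(
        individuals_total=total,
        by_class={c: _stat(class_counts[c], total) for c in CLASS_ORDER},
        by_exporter=_country_tally(scored, lambda s: s.adjusted.record.exporter, total),
        by_importer=_country_tally(scored, lambda s: s.adjusted.record.importer, total),
        by_trade_category=dict(sorted(cat_counts.items(), key=lambda kv: (-kv[1], kv[0]))),
    )


def scenario_no_option_range(scored: Sequence[ScoredRecord]) -> tuple[int, int]:
    """(min, max) individuals scored 'no option' under clade ambiguity.

    Run on records scored with ``assume_country_clade_for_captive=True``:
    the minimum counts individuals whose *best* case is still 'no option';
    the maximum adds those whose *worst* case is (multi-clade release-site
    ambiguity, e.g. a DRC-bound record).
    """
    lo = sum(s.quantity for s in scored if s.best_score.level == SuitabilityLevel.NO_OPTION)
    hi = sum(s.quantity for s in scored if s.worst_score.level == SuitabilityLevel.NO_OPTION)
    return lo, hi


# ---------------------------------------------------------------------------
# Flow edges and report export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowEdge:
    exporter: str
    importer: str
    trade_category: str
    suitability_class: str
    individuals: int


def flow_edges(scored: Sequence[ScoredRecord]) -> list[FlowEdge]:
    """Aggregate scored records into exporter→importer flow edges."""
    agg: dict[tuple[str, str, str, str], int] = {}
    for s in scored:
        key = (
            s.adjusted.record.exporter,
            s.adjusted.record.importer,
            s.adjusted.category.name if s.adjusted.category else "UNCATEGORISED",
            s.suitability_class(),
        )
        agg[key] = agg.get(key, 0) + s.quantity
    return [
        FlowEdge(*key, individuals=n) for key, n in sorted(agg.items())
    ]


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def export_reports(
    summary: SuitabilitySummary,
    edges: Sequence[FlowEdge],
    out_dir: str | Path,
    *,
    run_info: dict | None = None,
    input_paths: Sequence[str | Path] = (),
) -> dict[str, Path]:
    """Write summary JSON, per-country CSV, flow-edge CSV and a run log.

    Output is deterministic for fixed input (sorted keys, stable ordering).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary_payload = {
        "individuals_total": summary.individuals_total,
        "by_class": {
            c: {"count": st.count, "percent": st.percent, "fraction": st.fraction}
            for c, st in summary.by_class.items()
        },
        "by_trade_category": summary.by_trade_category,
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary_payload, indent=1), encoding="utf-8")

    rows = []
    for role, table in (("exporter", summary.by_exporter), ("importer", summary.by_importer)):
        for country, (n, frac, breakdown) in table.items():
            rows.append(
                {
                    "role": role,
                    "country": country,
                    "individuals": n,
                    "fraction": round(frac, 6),
                    **{f"class_{c}": breakdown.get(c, 0) for c in CLASS_ORDER},
                }
            )
    paths["per_country"] = out / "per_country.csv"
    pd.DataFrame(rows).to_csv(paths["per_country"], index=False, encoding="utf-8")

    paths["flows"] = out / "flow_edges.csv"
    pd.DataFrame([e.__dict__ for e in edges]).to_csv(paths["flows"], index=False, encoding="utf-8")

    log = dict(run_info or {})
    log["input_digests"] = {str(p): _digest(p) for p in input_paths}
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=1, sort_keys=True), encoding="utf-8")
    return paths
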