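"""Hierarchical translocation-suitability scoring.

A source/target pair of lion populations is ranked on four ordered levels:

* **first choice** — same nuclear clade and same mtDNA haplogroup;
* **second choice** — same nuclear clade, differentiated mtDNA;
* **third choice** — different nuclear clades within *P. l. melanochaita*;
* **no option** — crossing subspecies, any move involving the strongly
  differentiated Indian population, cross-nuclear-clade moves within
  *P. l. leo*, or individuals of unknown genetic origin.

Two modifiers sit on top of the level: populations of human-mediated
hybrid origin are flagged ("faded") rather than demoted, and around
natural suture zones the matrix is asymmetric — moving *into* a suture
zone (best case over the zone's component clades) is more favourable
than moving *from* one (worst case, since hybrid individuals may be
sourced).
"""

from __future__ import annotations

import enum
import functools
import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .registry import (
    CladeVocabulary,
    GeneticProfile,
    LCURecord,
    Registry,
    RegistryError,
    country_profile,
)

__all__ = [
    "SuitabilityLevel",
    "SuitabilityScore",
    "SuitabilityMatrix",
    "score_pair",
    "apply_suture_direction",
    "score",
    "build_matrix",
    "write_matrix",
    "read_matrix",
]


@functools.total_ordering
class SuitabilityLevel(enum.Enum):
    """Ordered suitability levels, FIRST > SECOND > THIRD > NO_OPTION."""

    NO_OPTION = 0
    THIRD = 1
    SECOND = 2
    FIRST = 3

    def __lt__(self, other: "SuitabilityLevel") -> bool:
        if not isinstance(other, SuitabilityLevel):
            return NotImplemented
        return self.value < other.value


@dataclass(frozen=True)
class SuitabilityScore:
    """A suitability level plus modifier flags and the rule that fired."""

    level: SuitabilityLevel
    hybrid_source: bool = False
    w2_source: bool = False
    suture_into: bool = False
    suture_from: bool = False
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.suture_into and self.suture_from:
            raise ValueError("suture_into and suture_from are mutually exclusive")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")

    @property
    def flags(self) -> tuple[str, ...]:
        out = []
        if self.hybrid_source:
            out.append("hybrid")
        if self.w2_source:
            out.append("w2")
        if self.suture_into:
            out.append("into_suture")
        if self.suture_from:
            out.append("from_suture")
        return tuple(out)

    def token(self) -> str:
        """Compact text form, e.g. ``SECOND;hybrid;into_suture``."""
        return ";".join((self.level.name,) + self.flags)


def _profile_level(
    a: GeneticProfile, b: GeneticProfile, vocabulary: CladeVocabulary
) -> tuple[SuitabilityLevel, str]:
    """Decision-tree core on a pair of genetic profiles (rule order R1-R5)."""
    a_india = "India" in a.nudna
    b_india = "India" in b.nudna
    if a_india != b_india:
        return (
            SuitabilityLevel.NO_OPTION,
            "R1: India rule — moves between the Indian population and African clades are excluded",
        )
    shared_nu = a.nudna & b.nudna
    if shared_nu:
        if a.mtdna & b.mtdna:
            return (SuitabilityLevel.FIRST, "R2: shared nuDNA clade and shared mtDNA haplogroup")
        return (
            SuitabilityLevel.SECOND,
            "R3: shared nuDNA clade, differentiated mtDNA haplogroups",
        )
    shared_sub = a.subspecies(vocabulary) & b.subspecies(vocabulary)
    if "melanochaita" in shared_sub:
        return (
            SuitabilityLevel.THIRD,
            "R4: differentiated nuDNA clades within P. l. melanochaita",
        )
    return (
        SuitabilityLevel.NO_OPTION,
        "R5: no shared nuDNA clade and no melanochaita subspecies match",
    )


def score_pair(
    source: LCURecord, target: LCURecord, vocabulary: CladeVocabulary
) -> SuitabilityScore:
    """Score a source/target LCU pair on the decision tree (no suture logic).

    Hybrid-origin and managed-metapopulation sources are flagged, not
    demoted: such populations may still be usable given per-individual
    genetic testing.
    """
    for rec in (source, target):
        try:
            rec.profile.validate(vocabulary)
        except RegistryError as exc:
            raise RegistryError(f"vocabulary mismatch for record {rec.id}: {exc}") from exc
    level, why = _profile_level(source.profile, target.profile, vocabulary)
    if source.suture_zone == "SZ1" and target.suture_zone == "SZ1":
        why += "; advisory: prioritise P. l. leo individuals in the subspecies suture zone"
    return SuitabilityScore(
        level=level,
        hybrid_source=source.hybrid_origin,
        w2_source=source.managed_metapopulation,
        rationale=why,
    )


def _components(record: LCURecord) -> list[GeneticProfile]:
    """Per-clade component profiles of a suture-zone record.

    The nuclear labels are split one per component; the full mtDNA set is
    retained on each, since haplogroup membership of individuals inside
    the zone is not resolved at registry level.
    """
    return [
        GeneticProfile(mtdna=record.profile.mtdna, nudna=frozenset({nu}))
        for nu in sorted(record.profile.nudna)
    ]


def apply_suture_direction(
    score: SuitabilityScore,
    source: LCURecord,
    target: LCURecord,
    vocabulary: CladeVocabulary,
) -> SuitabilityScore:
    """Apply the directional suture-zone asymmetry to a computed score.

    Movement into a suture zone by a source sharing a nuclear clade with
    the zone takes the *best* level over the zone's component clades;
    movement out of a suture zone takes the *worst* (possible hybrid
    individuals). Two records in the same zone pair as FIRST — the zone
    itself is the recommended source.
    """
    src_sz, tgt_sz = source.suture_zone, target.suture_zone
    if src_sz is None and tgt_sz is None:
        return score
    if src_sz is not None and tgt_sz is not None:
        if src_sz == tgt_sz:
            return replace(
                score,
                level=SuitabilityLevel.FIRST,
                rationale="same suture zone: source individuals from within the zone preferred",
            )
        return score  # cross-suture pair: keep the profile-intersection score
    if tgt_sz is not None:
        if not (source.profile.nudna & target.profile.nudna):
            return score
        best = max(
            _profile_level(source.profile, comp, vocabulary)[0]
            for comp in _components(target)
        )
        return replace(
            score,
            level=best,
            suture_into=True,
            suture_from=False,
            rationale=score.rationale
            + f"; into suture zone {tgt_sz}: best case over component clades",
        )
    worst = min(
        _profile_level(comp, target.profile, vocabulary)[0] for comp in _components(source)
    )
    return replace(
        score,
        level=worst,
        suture_from=True,
        suture_into=False,
        rationale=score.rationale
        + f"; from suture zone {src_sz}: worst case, possible hybrid individuals",
    )


def score(
    source: LCURecord, target: LCURecord, vocabulary: CladeVocabulary
) -> SuitabilityScore:
    """Full pairwise score: decision tree followed by suture directionality."""
    return apply_suture_direction(score_pair(source, target, vocabulary), source, target, vocabulary)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


@dataclass
class SuitabilityMatrix:
    """Complete source × target matrix over LCUs or countries."""

    axis: list[str]
    cells: dict[tuple[str, str], SuitabilityScore]
    axis_kind: str = "lcu"

    def __getitem__(self, key: tuple[str, str]) -> SuitabilityScore:
        return self.cells[key]


def _country_cell(
    registry: Registry, src_country: str, tgt_country: str
) -> SuitabilityScore:
    """Best-case score over all extant LCU pairs of two countries.

    Multi-clade countries make the cell ambiguous; the best-case level is
    stored and the worst case retained in the rationale, mirroring how
    release-site ambiguity (e.g. the DRC) propagates a range rather than a
    point in the audit.
    """
    vocab = registry.vocabulary
    src_recs = registry.records_for_country(src_country)
    tgt_recs = registry.records_for_country(tgt_country)
    scored = [score(s, t, vocab) for s in src_recs for t in tgt_recs]
    best = max(scored, key=lambda sc: sc.level)
    worst = min(sc.level for sc in scored)
    multi = (
        country_profile(registry, src_country).multi_clade
        or country_profile(registry, tgt_country).multi_clade
    )
    rationale = best.rationale
    if multi and worst != best.level:
        rationale += f"; multi-clade country: worst case {worst.name}"
    elif multi:
        rationale += "; multi-clade country"
    return replace(best, rationale=rationale)


def build_matrix(registry: Registry, axis: str = "lcu") -> SuitabilityMatrix:
    """Build the complete asymmetric suitability matrix.

    ``axis='lcu'`` scores every pair of extant LCU records; ``axis='country'``
    aggregates per country (best case over LCU pairs, multi-clade ambiguity
    noted in the rationale).
    """
    if axis not in ("lcu", "country"):
        raise ValueError("axis must be 'lcu' or 'country'")
    extant = [r for r in registry.records if r.extant]
    if not extant:
        raise RegistryError("cannot build a matrix from an empty registry")
    vocab = registry.vocabulary
    cells: dict[tuple[str, str], SuitabilityScore] = {}
    if axis == "lcu":
        labels = [r.id for r in extant]
        for s in extant:
            for t in extant:
                cells[(s.id, t.id)] = score(s, t, vocab)
    else:
        labels = sorted({c for r in extant for c in r.countries})
        for sc in labels:
            for tc in labels:
                cells[(sc, tc)] = _country_cell(registry, sc, tc)
    return SuitabilityMatrix(axis=labels, cells=cells, axis_kind=axis)


def write_matrix(matrix: SuitabilityMatrix, path: str | Path, format: str = "csv") -> Path:
    """Write a matrix as CSV (level tokens + flag suffixes) or JSON (full scores)."""
    out = Path(path)
    if format == "csv":
        df = pd.DataFrame(
            [[matrix.cells[(s, t)].token() for t in matrix.axis] for s in matrix.axis],
            index=matrix.axis,
            columns=matrix.axis,
        )
        df.to_csv(out, index_label="source\\target", encoding="utf-8")
    elif format == "json":
        payload = {
            "axis": matrix.axis,
            "axis_kind": matrix.axis_kind,
            "cells": {
                f"{s}->{t}": {
                    "level": sc.level.name,
                    "hybrid_source": sc.hybrid_source,
                    "w2_source": sc.w2_source,
                    "suture_into": sc.suture_into,
                    "suture_from": sc.suture_from,
                    "rationale": sc.rationale,
                }
                for (s, t), sc in sorted(matrix.cells.items())
            },
        }
        out.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError("format must be 'csv' or 'json'")
    return out


def read_matrix(path: str | Path) -> SuitabilityMatrix:
    """Read a matrix written by :func:`write_matrix` (JSON round-trips fully;
    CSV recovers levels and flags, rationale reduced to the cell token)."""
    p = Path(path)
    if p.suffix == ".json":
        payload = json.loads(p.read_text(encoding="utf-8"))
        cells = {}
        for key, sc in payload["cells"].items():
            s, t = key.split("->", 1)
            cells[(s, t)] = SuitabilityScore(
                level=SuitabilityLevel[sc["level"]],
                hybrid_source=sc["hybrid_source"],
                w2_source=sc["w2_source"],
                suture_into=sc["suture_into"],
                suture_from=sc["suture_from"],
                rationale=sc["rationale"],
            )
        return SuitabilityMatrix(axis=list(payload["axis"]), cells=cells, axis_kind=payload["axis_kind"])
    df = pd.read_csv(p, index_col=0, dtype=str)
    axis = [str(c) for c in df.columns]
    cells = {}
    for s in df.index:
        for t in axis:
            token = str(df.loc[s, t])
            parts = token.split(";")
            cells[(str(s), t)] = SuitabilityScore(
                level=SuitabilityLevel[parts[0]],
                hybrid_source="hybrid" in parts,
                w2_source="w2" in parts,
                suture_into="into_suture" in parts,
                suture_from="from_suture" in parts,
                rationale=token,
            )
    return SuitabilityMatrix(axis=axis, cells=cells, axis_kind="unknown")
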