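# Methods

## The classification model

The package treats translocation suitability as a deterministic function
of clade assignment. A population (lion conservation unit, LCU) carries a
set of mtDNA haplogroup labels and a set of nuclear-clade labels; the
nuclear clade determines the subspecies (*P. l. leo*: West, Central,
India; *P. l. melanochaita*: East, Southern). For a source/target pair
the rules fire in fixed precedence:

1. **India exclusion** — if exactly one side carries the India nuclear
   clade, the pair is *no option*, regardless of the shared subspecies.
   Putting this rule first guarantees it cannot be bypassed by the
   shared-subspecies path.
2. Shared nuclear label **and** shared mtDNA label → *first choice*.
3. Shared nuclear label, disjoint mtDNA labels → *second choice*.
4. Disjoint nuclear labels but a shared *melanochaita* subspecies →
   *third choice*.
5. Otherwise *no option*. This includes West ↔ Central moves inside
   *P. l. leo*: a third-choice tier exists only within *melanochaita*,
   so cross-nuclear moves within *leo* fall through to rule 5. This
   reading is implemented literally; cells where a softer treatment
   could be argued are distinguishable by their rationale string.

"Shared" always means non-empty set intersection. This is what makes
multi-label profiles work: a KAZA population carrying both East/Southern
and South West haplotypes scores *first choice* against either parent
haplogroup.

Assumptions: clade assignments are inputs, not inferences — no sequence
data are touched; country-level attribution assumes the country's
recorded LCUs exhaust its wild populations; certainty grades (high /
fairly high / medium) are carried as metadata and do not alter levels.

## Suture zones and hybrid populations

Suture-zone records carry ≥2 nuclear labels. Directionality is applied
after the base level: *into* a zone (source shares a nuclear clade with
the zone) takes the **best** level over the zone's component clades;
*from* a zone takes the **worst**; two records in the same zone pair as
*first choice*. Component profiles are formed by splitting the nuclear
labels one per component while retaining the full mtDNA set — individual
haplogroup membership inside a zone is unresolved at registry level, so
mtDNA is not partitioned. Pairs spanning two *different* suture zones
keep their plain intersection score; flags stay unset (a case the
qualitative asymmetry rule does not cover).

Hybrid-origin populations retain their nominal clade labels plus the
introgressed mtDNA labels, and every score sourced from them carries
`hybrid_source=true` ("faded") instead of a demotion: downstream
consumers decide whether per-individual testing is feasible. The SZ1
recommendation to prioritise *P. l. leo* individuals is emitted as an
advisory note in the rationale, not as a level change.

## The packaged default registry

The packaged table is a ~30-row, country-level approximation labelled as
such: it encodes only facts stated at country resolution (suture-zone
membership, the KAZA mtDNA overlap across Botswana/Zambia/Zimbabwe —
deliberately excluding Namibia, where only Etosha is modelled —, hybrid
flags for Greater Kruger, the RSA managed metapopulation, Zimbabwe's
lowveld, Eswatini, Rwanda, Malawi and Lake Nakuru–Soysambu, the
two-clade DRC and Kenya splits, and the Batéké population's South West
haplotype affinity). The full 132-LCU table can be loaded from CSV with
the same schema and replaces the default transparently; all scoring code
is agnostic to registry size.

## Trade-record handling

Quantities: importer- and exporter-reported figures are reconciled to
their **maximum** (permits record intended maxima; an exporter-preferred
rule is available via `quantity_rule="exporter"`). Filtering keeps
live-term lion records, years 1983–2019, importers within the
configurable range-state list, purposes {N, T, B, H} and sources
{W, F, R, C, blank}; every exclusion is tallied (records and
individuals) so counts are conserved, and blank purposes are excluded
rather than guessed.

Source-class adjustment precedence: override table → F/R ⇒ W2 → ZA 'W'
post-2005 ⇒ W2 → ZA blank pre-cutoff ⇒ W1 → ZA blank otherwise ⇒ W2 →
W ⇒ W1 → C ⇒ C → else U. The "mid-1990s" cutoff defaults to 1995
(fenced reserves date from 1991; captive facilities were rare pre-1994)
and is configurable. F/R ⇒ W2 applies to all exporters by default — the
rule as stated is unscoped — with a switch restricting it to South
Africa for sensitivity analysis. Overrides are an explicit CSV
(exporter, importer, year range, class, citation) so grey-literature
reclassifications such as the Akagera restocking stay auditable. When an
origin country differing from the exporter is present, origin wins for
genetic attribution (the exporter may be a transit state).

Records with a blank raw source code fall outside the 4×4
source×purpose categorisation domain; their trade category is derived
from the adjusted class instead (W1/W2 → wild, U → uncategorised).

## Pipeline scoring

Captive (C) and unknown (U) individuals are *no option* unconditionally
— their genetic background is unknown. W2 individuals are reported as a
fifth, parallel class (their clade-based level is still computed and
available). Wild individuals are scored over the **cartesian product of
candidate LCU pairs** of the attributed source country and the importer,
yielding a best/worst interval; multi-clade countries (DRC, Kenya,
Nigeria, …) are exactly the cases where the interval is non-degenerate.
The `assume_country_clade_for_captive` scenario scores captive stock by
its exporting country's profile; the resulting 'no option' count is then
an interval: minimum = individuals whose *best* case is still no option,
maximum adds those whose *worst* case is. Percentages are reported
quantity-weighted (per individual) and rounded to whole percent for
report parity, with raw fractions also emitted; the permit-weighted
alternative is a one-line change on the summary but is not the default.

## Synthetic data

The generator exists so every pipeline property is testable without any
download. Registries: configurable clade vocabulary (`Mt1…`, `Nu1…`),
subspecies split, suture and hybrid probabilities; ground truth is
emitted as a sidecar keyed by record id. Trade tables: each record's
intended source class drives the emitted codes (F/R for W2, reserved
exporter for override-covered records, pseudo-code XX for unknown), so
recovery checks are exact rather than statistical; malformed rows
(non-numeric years) and out-of-scope rows (non-live terms, non-range
importers) are injected only on request and flagged in the ground truth.
Permit sizes default to a truncated geometric with mean 2 (live-animal
permits are small).

The **replication profile** is an explicit cell table over (exporter,
importer, source, purpose, year window) whose expected marginals equal
the published audit composition: 1056 individuals (one per permit row,
so shares read directly), 848 captive-coded (81%), 772 captive after
adjustment (73%; 290 from outside range states, 2 unknown), 106 W2
(10%), 342 South African exports (32%), and 66/97/15 wild individuals
over first/second/third choice (6/9/1%). The published joint
composition is not available, so the cell table is one consistent
solution to those marginals; South African *imports* come out ≈607
(57%) against the published 638 (60%) — with every other stated
marginal fixed there is no flow left that could be routed into South
Africa without breaking one of them. Under the captive-scenario the
design yields a 382–412 'no option' interval (the interval arises from
30 DRC-bound captive individuals whose release-site clade is ambiguous,
plus 90 cross-subspecies captive exports and the 292 individuals from
outside the range or of unknown origin). Actual runs draw cells
multinomially, so realised counts vary around these expectations with
binomial sampling error (±1–1.5 percentage points at n=1056).

What the generator does **not** emulate: year-by-year trade dynamics,
re-export chains, unreported/illegal trade, permit-level quantity
inflation, or LCU-resolution release sites. Passing tests therefore
demonstrate the correctness of the classification and accounting
machinery under the designed composition — not the fidelity of the
packaged country-level registry to any particular supplementary table.

## Problem sizes and numerics

The test suite enumerates the decision tree exhaustively over a small
vocabulary (60 unit types → 3600 ordered pairs) against an independent
truth-table oracle; record-level recovery runs at n = 10,000; the
replication checks at the audit's own n = 1056. All randomness flows
through `numpy.random.default_rng` seeds; identical parameters give
byte-identical CSV outputs. Quantities are integerised by ceiling
(a permit listing 0.5 of a lion does not occur; fractional inputs are
treated as at-least-one). Summary orderings are count-descending then
alphabetical, making every export deterministic.

## Known limitations

* The packaged registry is a country-level approximation; per-LCU
  suitability around suture zones and hybrid populations may differ from
  expert-curated per-cell assignments, and such cells are recognisable
  by their suture/hybrid flags rather than asserted equal.
* Whether cross-nuclear moves within *P. l. leo* deserve an intermediate
  tier is genuinely open; the package scores them *no option* (see rule
  5 above).
* The trade audit counts permit-intended maxima, not realised
  translocations, and only international, documented trade.
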