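# lionmatch

Genetic decision support for lion (*Panthera leo*) conservation
translocations, and a CITES live-lion trade audit built on top of it.

Lion populations fall into well-characterised genetic clades: six
mitochondrial haplogroups (West, Central, North East, East/Southern,
South West, India) and five nuclear clades (West, Central, East,
Southern, India), the latter mapping onto the two subspecies *P. l. leo*
(West + Central Africa and India) and *P. l. melanochaita* (East +
Southern Africa). Translocations that ignore this structure risk eroding
it — mixing differentiated clades homogenises diversity and can disrupt
local adaptation. `lionmatch` encodes the structure in a population
registry and ranks any source/target pair on an ordered scale:

| level | rule |
|---|---|
| **first choice** | same nuDNA clade and same mtDNA haplogroup |
| **second choice** | same nuDNA clade, differentiated mtDNA |
| **third choice** | different nuDNA clades within *P. l. melanochaita* |
| **no option** | crossing subspecies, any Africa ↔ India move, cross-nuclear moves within *P. l. leo*, or unknown genetic origin |

Two modifiers refine the scale. Populations with human-mediated hybrid
ancestry (e.g. the Greater Kruger area after Etosha-sourced
introductions) are *flagged* rather than demoted — individuals may still
qualify after genetic testing. Around the two natural suture zones
(SZ1: Sudan/South Sudan/Ethiopia; SZ2: Zambia/Malawi/Mozambique) the
matrix is deliberately asymmetric: moving *into* a zone scores the best
case over the zone's component clades, moving *from* one the worst case,
since out-going individuals may be natural hybrids.

The trade audit applies this scale to CITES Trade Database
comparative-tabulation exports: live lions imported into range states
(1983–2019, purposes N/T/B/H, sources W/F/R/C or blank), quantities
reconciled to the permit-intended maximum, and South African source
codes re-examined — F/R-coded and post-2005 'W' exports, plus
specifically overridden flows, are reclassified to the managed
metapopulation class **W2**, reported as its own (fifth) category.

## Worked example

Generate a synthetic 200-permit trade table from the replication profile
and audit it:

```bash
lionmatch simulate --profile replication --n 200 --seed 4 --out demo/
lionmatch summarize --cites demo/cites_trade.csv --overrides demo/overrides.csv
```

```json
{
 "individuals_total": 200,
 "by_class": {
  "FIRST": {"count": 11, "percent": 6},
  "SECOND": {"count": 25, "percent": 12},
  "THIRD": {"count": 6, "percent": 3},
  "W2": {"count": 22, "percent": 11},
  "NO_OPTION": {"count": 136, "percent": 68}
 }
}
```

Of 200 permitted individuals, 136 (68%) are 'no option' — almost all
captive-sourced stock of unknown genetic background — 22 (11%) come from
the South African managed metapopulation (W2), and only 11 (6%) are
first-choice moves between populations of the same nuclear clade and
haplogroup. `lionmatch score-trade` writes the full per-record audit
(`adjusted_records.csv`), per-country tables and exporter→importer flow
edges. The country-level suitability matrix itself comes from

```bash
lionmatch build-matrix --axis country --out matrix.csv
```

whose cells carry level tokens plus flags, e.g. Angola → Mozambique is
`SECOND;into_suture` (same Southern nuclear clade, differentiated
haplogroup, scored into suture zone 2 as the best case over the zone's
component clades).

The same functionality is available as a library
(`lionmatch.score`, `build_matrix`, `read_cites_csv`, `filter_records`,
`adjust_records`, `score_records`, `summarize`), and the registry CSV
schema is: `id, name, countries, mtdna, nudna, certainty, suture_zone,
hybrid_origin, managed_metapopulation, extant, notes` with `|`-separated
multi-valued cells and ISO-3166 alpha-2 country codes (informal names
such as "RSA" are accepted on input).

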