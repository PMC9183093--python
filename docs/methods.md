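# Methods

## The identification model

The key is *subtractive* and *multi-access*: the flora is a trait matrix
(taxa in rows, characters in columns) and identification is the progressive
intersection of the full taxon set with the set compatible with each
answered character. Formally, with answer sheet `O` and candidate set
`C_0` = all taxa,

```
C_{k+1} = C_k ∩ { t : match(o_{k+1}, t) }        (answered steps)
C_{k+1} = C_k                                    (skipped steps)
```

The terminal set may hold 0, 1 or several taxa; all three are reported as
`no_match`, `determined`, `ambiguous`. Ambiguity is deliberately *not*
resolved by the engine — choosing among a handful of candidates (e.g. from
photographs) is a human step, and ranking heuristics would add false
confidence.

Assumptions baked into the model:

- **Point observations.** A user measures one specimen, so an observation
  is a point value compared against the taxon's stored [min, max] interval.
  Interval-vs-interval overlap is out of scope.
- **Closed intervals, symmetric slack.** Stored bounds are inclusive; the
  per-character absolute slack `s` widens both ends (`[min − s, max + s]`).
  The default slack is 0 because a curated key database is expected to carry
  deliberately loosened ("forgiving") borders already; slack exists for
  noisy field measurements on top of that.
- **Forgiving missing data.** A missing cell (or bound) matches anything.
  This trades selectivity for robustness: a data gap in the matrix can
  produce residual ambiguity but never a false exclusion.
- **Circular phenology.** Flowering windows are month pairs on a circle;
  `since > until` wraps the year boundary (Nov–Feb = {11, 12, 1, 2}).
  Months are integers 1–12; the source data carry no day resolution.
- **Determinism.** The engine contains no randomness and never reorders
  questions; question order belongs to the caller, and the terminal set is
  provably order-independent (conjunction is commutative) — property-tested
  rather than assumed.

Consequences used as test oracles: monotone shrinkage of the candidate
list, skip-neutrality, order-independence, slack-monotonicity (more slack
never shrinks the terminal set), and equality of progressive filtering with
a one-pass brute-force scan that evaluates the full conjunction per row.

## The trait schema

The default schema has 31 columns: the taxon name plus 30 characters in
fixed order — eight quantitative min/max pairs (altitude in m a.s.l.,
height in cm, leaflet count [integer], leaflet width/length in mm, flowers
per inflorescence [integer], flowerhead length and corolla length in mm),
one circular flowering-month window, nine qualitative characters (leaf
shape, leaflet shape, inflorescence type, corolla color, legume type,
habitat, substrate, abundance, endemism) and three free-text note columns
searched by substring. Units are fixed per column and never stored in
cells.

Parsing conventions (CSV, UTF-8, header row): empty cells and `NA` are
missing; a missing bound of a pair means unbounded on that side;
multi-valued qualitative cells split on `;` with tokens trimmed,
case-folded and whitespace-collapsed (normalization is idempotent). A YAML
configuration can override the delimiter, the missing tokens and per-column
closed vocabularies; with a closed vocabulary, validation flags
out-of-vocabulary cell tokens as errors and the engine logs a warning when
a *user's* answer is outside the vocabulary (the answer still filters —
it simply matches no closed cell).

Validation is total and non-throwing: `validate_matrix` returns findings
(row, column, severity, message) for inverted pairs, out-of-range months,
vocabulary violations and duplicate taxon names; an empty error list is
exactly equivalent to all row invariants holding.

## Occurrence tallies

Records are (plant, bacterium, category, source) with categories
`symbiont`, `nodule_endophyte`, `tissue_endophyte`. Tallies count records;
`count_distinct_taxa`, promiscuity and host range count distinct normalized
name strings. Genus extraction is the first whitespace token; `Genus sp.`
is its own species-rank label; biovars are not modelled as separate taxa.
Plant names pass through a transitive, cycle-checked synonym table at load
time (former name → current name; current names are fixed points).

The packaged reference tables are transcriptions of a published survey of
bacteria associated with the Sardinian legume flora. They are *marginal*
counts — the record-level association spreadsheet behind them is not
public — so `expand_counts` rebuilds record-level tables with deterministic
synthetic placeholder partners; tallying an expanded table reproduces the
source counts exactly, which is the round-trip invariant the tests check.
Because partners are placeholders, promiscuity and host-range summaries are
*not* meaningful on expanded reference tables and are validated on synthetic
tables against brute-force set-size oracles instead.

Transcription caveats (also documented in `botakey.fixtures`):

- The symbiont table has two layers. The printed genus totals (13 genera,
  sum 241) are authoritative; the 74 species rows sum to 242 because the
  printed Rhizobium species rows exceed their genus total by one, and one
  Mesorhizobium species count, blank in print, is restored as 1 by
  subtraction from its printed genus total.
- The nodule-endophyte list repeats three labels (Paenibacillus sp.,
  Stenotrophomonas sp., Streptomyces sp.) that evidently denote distinct
  taxa sharing a printed name; its *entry count* is 142 while its
  distinct-label count is 139. Distinctness by name string is the only
  operation the data supports.
- The per-plant table holds 104 species rows whose per-genus sums all match
  their printed genus totals (grand total 543 occurrences).

## Synthetic data

The generators exist to exercise contracts, not to mimic Sardinian trait
distributions. `generate_flora` draws, per taxon and per character pair, an
interval midpoint uniformly within a per-character scale chosen to be
realistic in that character's units (altitude 0–1800 m a.s.l., height
5–200 cm, leaflets 1–25, corolla 2–30 mm, …), a half-width up to a quarter
of the scale, and blanks cells independently at `missing_rate` (default
0.15; bounds of a pair blank together so pairs stay complete). Flowering
windows wrap the year boundary with probability 0.15 — autumn-to-spring
flowering is common in a Mediterranean flora. Qualitative cells draw 1–3
tokens from fixed botanical vocabularies; binomials are built from fixed
syllable lists, unique per flora. All generators take an explicit integer
seed into a private `numpy.random.Generator`; identical configuration gives
byte-identical serialization, and there is no global random state.

`draw_specimen` answers each character the taxon has data for with
probability `answer_rate`, drawing numeric values uniformly inside the
stored interval and perturbing them by a uniform error in `[-noise,
+noise]`; months are drawn inside the circular window, categorical answers
pick a stored token, text answers pick one word of the stored note. By
construction a specimen at `noise = 0` satisfies its source taxon at slack
0, and at noise `ε` at slack ≥ `ε` — the retention property the acceptance
suite measures (100 floras × 5 specimens at noise 0, 0.1 and 0.5 with
matched slack).

What passing these tests shows — and does not. The synthetic floras have
independent, uniformly scattered characters, so they are *easier* to
discriminate than a real flora with correlated traits and clusters of
near-identical congeners; retention and oracle-equivalence results
establish the engine's logic, not an expected field identification rate.
Real keys also embed curatorial judgment (how loose the stored borders are)
that no generator reproduces.

## Problem sizes and numerical choices

The acceptance checks use 100 seeded floras up to 200 taxa for the oracle
equivalence scan and 100 floras × 5 specimens for retention — sizes at
which the whole suite runs in seconds while covering the schema's full
character mix. Numeric comparisons are plain floating-point with no
tolerance beyond the explicit slack: the only arithmetic is subtraction
and comparison, and the generators emit values rounded to one decimal, so
no epsilon machinery is warranted. Tie-breaks are lexical: tallies sort
alphabetically, host ranges by descending count then alphabetically.
Degenerate inputs are first-class: empty matrices, header-only files,
zero-record tables, empty answer sheets (which keep the full flora) and
single-bound pairs are all tested paths.

## Known limitations

- No best-next-question ranking, no fuzzy string matching beyond
  normalization and substring containment, no dichotomous-key mode.
- Distinctness of bacterial taxa is by name string; strains sharing a
  printed `Genus sp.` label merge in distinct counts.
- The optional spreadsheet import of the original workbook format is not
  implemented; CSV is the canonical contract.
- Promiscuity/host-range on expanded marginal tables reflect placeholder
  partners, not biology (see above).
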