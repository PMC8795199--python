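# Methods

This note documents the models, rules, and numerical choices behind
`c14scrub`, and what the synthetic fixtures do and do not establish about
real data.

## Record model and schema

A record is one radiocarbon measurement: an uncalibrated age and one-sigma
error in ¹⁴C years BP, a laboratory number whose alphabetic prefix
identifies the dating laboratory, optional δ13C (‰), material/taxon
metadata, WGS84 coordinates with an ordinal location-accuracy grade
(`LocAccuracy`: 0 = country-level only … 3 = exact collector-provided
location), and provenance (source compilation, reference). All cells are
carried as text; each cleaning stage parses exactly the fields it rules
on, so nothing is coerced (or lost) before the rule that owns it fires.
Output is always UTF-8 — locale-encoding fallbacks are the mechanism that
corrupts site names in the first place, so the writer has none.

Non-integer handling: a cell like `1050.0` is treated as the integer 1050
(a common CSV artifact that changes no value), while `1050.5` is a genuine
non-integer age and is removed — sub-year resolution overstates what the
measurement can know. The same reading applies to errors; the surviving
table therefore satisfies `age, error ∈ ℤ`, `0 < age ≤ 55,000`,
`15 ≤ error ≤ age` (all bounds configurable). Boundary readings are
literal: age 55,000, error 15, and error = age are all kept. A non-integer
error is removed under its own reason code: the stated survivors'
invariant requires integer errors, and silently rounding a measurement
uncertainty would fabricate precision.

## Laboratory-code registry

The purge rule is strict: a record whose `LabID` has no leading alphabetic
token, or whose token is not registered, cannot be traced to a laboratory
and is removed. Tokenization takes the letters before the first digit,
hyphen, space, slash, or other non-letter, case-insensitively, because
source compilations write the same laboratory as `Beta-`, `Beta ` and
`BETA`. The bundled registry holds 173 curated real-world prefixes with
laboratory name and country. We deliberately did not pad the file to a
larger row count: the registry's contract is lookup, and every invented
code would widen the purge's blind spot. Laboratories open, close, and
rename, so the registry is a starting point, replaceable via
`--registry`.

## Coordinates and location verification

`parse_coordinate` recognizes decimal degrees and
degrees/minutes[/seconds] with sign or hemisphere letter
(value = deg + min/60 + sec/3600, negated for S/W), and refuses everything
else — in particular projected Northing/Easting pairs, which cannot be
interpreted without zone metadata. Refusal clears the coordinates and
drops `LocAccuracy` to 0; the record survives, locationless.

Verification (opt-in, because it rewrites location fields and therefore
changes downstream counts) measures the distance from each point to its
listed admin unit: inside ⇒ untouched; ≤ 500 m ⇒ `LocAccuracy` capped at 2
(a rounding or GPS artifact); ≤ 10 km ⇒ capped at 1; beyond that the axes
are swapped and retested (a frequent data-entry error); failing that, a
US Smithsonian-trinomial `SiteID` can still place the record in a state
(province set, coordinates dropped, `LocAccuracy` 1); otherwise the
coordinates are dropped and `LocAccuracy` goes to 0. "Within" is read
inclusively (≤), and `LocAccuracy` never increases. Distances are
great-circle metres on a 6,371,000 m sphere against boundary vertices
densified to a configurable spacing (default 100 m), keeping the whole
contract projection-free; the densification error is bounded by half the
spacing. The Canadian Borden-grid block → province table is not bundled
(it requires the full grid gazetteer); the lookup format supports
user-supplied `borden` rows, and unmapped Borden identifiers fall through
to the coordinate-dropping branch.

## Duplicate cascade

Records sharing a (case- and whitespace-normalized) `LabID` are instances
of one physical measurement. The cascade, in order: (1) any disagreement
in age *or* error deletes the whole group — either conflict makes the true
measurement unrecoverable; (2) identical age and identical location
(coordinates equal after rounding to 4 decimals ≈ 11 m, or all absent)
merge into one record whose `Source` is the alphabetically sorted
concatenation of all distinct sources; (3) a member from a
higher-priority source wins (default priority: the systematically
collected compilation over the voluntary-submission database); (4) the
highest `LocAccuracy` wins; (5) remaining ties break on δ13C plausibility
(in [−30, −1] ‰ best; nonzero outside the band next; exactly 0 next —
several compilations used 0 for "missing"; absent last); (6) members
still tied whose coordinates differ by more than ±0.5° in either axis are
an unresolvable location conflict and the whole group is deleted. The
residual "arbitrary" choice is deterministic: lexicographically smallest
source, then first input position — so resolution is invariant under
input row order. The winner's coordinates are kept as-is (never averaged:
an average can fall in no admin unit). The fuzz-conflict rule is
evaluated last, among the final tied candidates, which by construction
share a `LocAccuracy`.

## Mojibake detection and repair

Corruption patterns are a data-driven regex list (replacement character;
Ã/Â followed by a non-ASCII character; â€/‚Ä pairs; the MacRoman √), not
a fixed constant: real corruption corpora are too diverse to enumerate
once. Repair is assisted, never automatic: a corpus of uncorrupted tokens
(from the tables plus any gazetteer word list; the tests use a small
synthetic gazetteer) supplies candidates within restricted
Damerau–Levenshtein distance 5 (substitution, insertion, deletion,
adjacent transposition — the metric spell-checking engines use), ranked by
(distance, frequency desc, lexicographic); the ranking criteria beyond
the distance bound are this package's choice. A human — or an answer
file, for reproducible runs — decides; Material and Reference fields are
only flagged, since their content cannot be inferred from the record.
Success on real tables therefore depends on corpus coverage and the
operator; the shipped tests establish the mechanics (bound, ranking,
determinism), not a field success rate.

## Geomasking

Protected records (matched by country — default USA and Canada — or by
source dataset) have their coordinates replaced by the geometric
(area-weighted) centroid of the containing admin unit; points just outside
every polygon (coasts, border rounding) snap to the nearest unit, ties
broken by smallest unit id. A geometric centroid can fall outside a
concave polygon; that is accepted — the obfuscation contract is
coarsening, not containment — and re-masking is a fixed point whenever
centroids do lie inside their units. Admin layers are GeoJSON
FeatureCollections (the ADM2 layers of public boundary databases ship in
this form); shapefile input is out of scope. Coordinate truncation, an
alternative obfuscation used by some sources, is not implemented —
centroid snapping is the single masking mode.

## Density surfaces and scaling fits

`kde2d` is a separable Gaussian product kernel evaluated on a regular
grid; the surface integrates to the total weight. Bandwidth defaults to
the per-axis normal-reference rule (σ·n^(−1/6), the d = 2 Silverman rule)
and is recorded in the output so any surface can be reproduced; densities
are computed on coordinates as given (planar approximation — adequate at
the regional scales the diagnostic targets, increasingly distorted toward
the poles). The risk surface normalizes numerator (dates-weighted) and
denominator (site) surfaces to unit mass before dividing, so ratio 1
means proportional sampling; cells with denominator below ε (default 1 %
of the denominator's maximum) are masked as noise.

Per-unit densities divide site and date counts by unit area; units with
zero sites are flagged and excluded from log fits (log of zero), with the
count reported. Log-log fits use base 10. The SMA fit is the closed form
slope = sign(r)·sd(y)/sd(x) through the centroid; zero variance on either
axis is an error, and an exactly-zero correlation would leave the sign
undefined (resolved as positive). No p-values are attached: spatial
autocorrelation between neighboring units invalidates the independence
they assume, so the slope is reported as a descriptive quantity.

The summary table rounds half-up (percent kept to 1 decimal, mean dates
per dated site to 2). The whole-table dated-site count is computed
globally, so it can be *smaller* than the sum of per-continent counts
(identical site keys on different continents collapse); the table reports
both numbers rather than reconciling them.

## Synthetic data: what it establishes

The generator produces schema-valid records with registered lab codes,
integer ages in (0, 55,000], errors in [15, min(age, 150)], and
coordinates on a rectangular admin grid with analytic centroids and
areas; a fictional gazetteer of countries and accented site names keeps
text-repair tests self-contained. `inject_errors` plants each error class
in exact counts on disjoint victim rows and logs every expected fate, so
a pipeline run can be checked record by record — the fixtures target
*rule coverage*, not statistical realism. Passing them shows the rules
fire exactly as specified on isolated, well-posed violations; it does not
show how often real compilations present compound or ambiguous
violations (a record both duplicated and mojibake-corrupted, coordinates
wrong in ways that still parse), nor anything about real spatial
sampling structure. All randomness flows through one seeded generator;
identical seeds give identical tables.

Problem sizes used by the default test run and the acceptance script —
twenty ~2,000-record pipelines, a 6,144-case duplicate enumeration,
15×15-grid kernel checks against brute-force summation, 100×50-unit SMA
recoveries per slope — were chosen as the smallest sizes at which each
check is decisive (exact equalities, 1e−10 agreement, ±0.1 slope
recovery).

## Known limitations

* The registry and the Smithsonian state table are curated
  reconstructions; completeness claims are explicitly not made.
* Cross-`LabID` duplicates (one sample measured by two laboratories)
  are not detected — no rule in the protocol addresses them.
* The verification stage automates a decision tree that was designed for
  supervised use; on boundary datasets with systematically wrong country
  labels it will relocate records a human might instead re-label.
* Normalized versus measured radiocarbon ages are indistinguishable in
  the schema (no flag exists), and implausible δ13C zeros are kept as-is;
  both follow the source-data conventions rather than fixing them.
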