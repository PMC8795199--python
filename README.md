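# c14scrub

Chronometric-hygiene scrubbing for archaeological radiocarbon-date tables,
with spatial sampling-bias diagnostics.

## The problem

Paleodemographers infer long-term human population change from the temporal
frequency of radiocarbon dates ("dates as data", summed probability
distributions). The raw material is a patchwork of regional compilations
that disagree in schema, coordinate formats, text encodings, and quality
control, and that report the same laboratory measurement many times over.
Before any demographic inference, such a compilation has to be *scrubbed*:
every record verified, every duplicate resolved, every anomaly removed —
and every removal documented, so that data contributors can see exactly why
a record did not survive.

`c14scrub` implements that scrubbing pipeline as a library plus a thin CLI,
for tables in the harmonized schema (`LabID`, `Age`, `Error`, `d13C`,
`Lat`/`Long`, `LocAccuracy` 0–3, `Country`/`Continent`, `SiteID`/`SiteName`,
`Source`, …). The stages, in fixed order:

1. **String sanitation** — quotation marks and commas are stripped from
   free-text fields (CSV-hostile characters corrupt downstream tooling).
2. **Laboratory-code purge** — the alphabetic prefix of each `LabID` is
   checked against a registry of known dating laboratories; unverifiable
   records are expunged.
3. **Coordinate standardization** — decimal-degree and
   degrees/minutes/seconds formats are detected and converted to WGS84
   decimal degrees; uninterpretable formats are cleared, never guessed.
   An opt-in verification stage tests each point against its listed
   country's boundary polygons (≤ 500 m off ⇒ `LocAccuracy` capped at 2;
   ≤ 10 km ⇒ capped at 1; farther ⇒ axes swapped and retested, then a
   US/Canada site-identifier fallback, then coordinates dropped).
4. **Duplicate resolution** — records sharing a `LabID` are one physical
   measurement. Conflicting ages delete the whole group; identical
   age + location merge into one record with concatenated sources;
   otherwise source priority, then highest `LocAccuracy`, then δ13C
   plausibility rank decide, and coordinates still disagreeing by more
   than ±0.5° delete the group.
5. **Anomaly filters** — missing/non-integer/non-positive ages, ages
   beyond the 55,000 BP calibration limit, errors below 15 yr or larger
   than the age, and mojibake-corrupted `LabID`s are removed, each under
   its own reason code.
6. **Geomasking** — coordinates of protected subsets (US/Canada records,
   password-protected source datasets) snap to the centroid of their
   administrative subdivision.

Every removal is routed to a *graveyard* table carrying the record, a
machine-groupable reason code, and the pipeline stage; for every run,
`|input| = |kept| + |graveyard|`.

Around the pipeline sit three diagnostic tools:

* **Continental summaries** — percent kept and mean dates per dated site
  (a *dated site* is a distinct `SiteName`/`SiteID`/`Lat`/`Long` tuple).
* **Risk surfaces** — the cellwise ratio of a dates-weighted 2D Gaussian
  kernel density to the plain site density, both normalized to unit mass:
  ratio 1 means dates are sampled proportionally to sites, >1
  over-sampling, <1 under-sampling.
* **SMA scaling** — standardized-major-axis fits of log₁₀ date density on
  log₁₀ site density per sampling unit. SMA is the symmetric fit whose
  slope magnitude is sd(y)/sd(x), appropriate because both axes carry
  sampling error; slope > 1 flags regions whose site-rich units are
  disproportionately dated.

A corrupted-text module rounds out the toolkit: it detects encoding
mojibake ("Barkåker" → "Bark√•ker") and ranks corrections from a corpus of
uncorrupted tokens within a bounded Damerau–Levenshtein distance, applied
interactively or through a reproducible answer file.

## Worked example

```python
import c14scrub as c

layer = c.generate_admin_grid(10, 10, 1.0)      # synthetic county grid
base = c.generate_clean(500, seed=42)           # schema-valid records
spec = c.ErrorSpec(unknown_lab=8, dms_coords=10, true_duplicates=6,
                   age_conflicts=4, location_conflicts=3, bad_error=5,
                   future_age=3, too_old=3, non_integer_age=3,
                   corrupt_text=4, mask_targets=10)
raw, truth = c.inject_errors(base, spec, seed=43, mask_layer=layer)
result = c.run_scrub(raw, c.PipelineConfig(mask_layer=layer))
```

This prints (see `examples/scrub_synthetic_table.py`):

```
input 513 -> kept 467, graveyard 46
  sanitize     in  513  removed   0
  labcodes     in  513  removed   8
  coordinates  in  505  removed   0
  dedup        in  505  removed  20
  filters      in  485  removed  18
  geomask      in  467  removed   0
graveyard reasons: {'UNKNOWN_LAB': 8, 'AGE_MISMATCH': 8, 'TRUE_DUPLICATE': 6,
 'LOCATION_CONFLICT': 6, 'AGE_TOO_OLD': 3, 'CORRUPT_LABID': 4,
 'ERROR_TOO_SMALL': 5, 'NON_INTEGER_AGE': 3, 'NONPOSITIVE_AGE': 3}
records whose fate deviates from the generator's truth log: 0
```

513 rows enter (500 generated + 13 appended duplicate instances); the 8
unknown-lab records die first, the 4 age-conflict pairs and 3 location
conflicts take both instances each, the 6 true duplicates lose one copy
each, and the filter rules remove exactly the injected counts. The final
line checks every record's fate — survival, graveyard reason, final
coordinates — against the generator's truth log: zero deviations.

The other `examples/` scripts each exercise one capability
(`summary_table.py`, `sampling_bias_surfaces.py`, `site_date_scaling.py`,
`fix_site_names.py`); each prints its numbers with a note on what they
mean. The same operations are available as CLI subcommands:

```sh
c14scrub scrub raw.csv -o scrubbed.csv -g graveyard.csv --report report.json
c14scrub fuzz scrubbed.csv -o public.csv --admin admin2.geojson
c14scrub summarize raw.csv scrubbed.csv -o summary.csv
c14scrub quality risk scrubbed.csv -o risk_grid.csv
c14scrub fixnames raw.csv -o fixed.csv --answers answers.tsv
c14scrub simulate -n 1000 --seed 1 -o synthetic.csv
```

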