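# Methods

## Model

The inference treats each arm of chromosome 11 as two zones separated by one
unknown changeover point: triplo-insensitive territory adjacent to the
centromere, then triplo-sensitive territory toward the telomere. Under this
assumption:

* a clinically normal carrier of a pericentric gain proves every covered base
  insensitive (the carrier tolerates three copies);
* a benign population CNV gain overlapping proven-insensitive territory
  extends the proof to its own outer boundaries (transitively, to a fixed
  point);
* a clinically abnormal carrier, or a pathogenic patient report, proves its
  gained territory reaches *at or beyond* the changeover point. This is an
  operational reading rather than a strict logical implication — a pathogenic
  report localizes a harmful gain without identifying the sensitive gene —
  and it is stated here explicitly because the windows are only derivable
  under it.

The minimal insensitive span is the outermost extent `[min start, max end]`
of the normal-carrier intervals, all of which must connect to the centromere
anchor (the union of the two acen bands, 51,600,001–55,700,000 in 1-based
GRCh37). If the union is not contiguous, the centromere-containing component
is returned with a gap warning. The sensitive-start window on 11p is
`[F_p, refined start]`, where `F_p` is the maximum coordinate covered by any
pathogenic record on the p side; 11q symmetrically. Coarse windows use only
in-cohort abnormal carriers: an abnormal interval extending beyond the span
on exactly one arm localizes its proven sensitive locus to that arm and
contributes its telomere-ward extreme; intervals extending on both arms are
ambiguous and contribute to neither (they prove a locus, but not on which
arm).

## Coordinate conventions

All coordinates are stored 1-based inclusive, as printed in case reports, so
every published number can be compared verbatim; conversion to 0-based
half-open happens only at the BED file boundary. Reported lengths follow the
printed convention `end − start` (no +1): the refined span 47,675,469 to
60,516,539 is reported as 12,841,070 bp = 12.84 Mb. The cytoband table is
the standard UCSC GRCh37 chromosome-11 ideogram, converted on load; the two
band edges that published case intervals pin down (51,600,000; 55,700,000)
are asserted in tests, the remaining edges are trusted fixture content.

## Evidence resolution

Per-case trisomy extents are resolved from parsed karyotypes as the union of
(a) a canonical-build (GRCh37) array interval and (b) the full spans of
gained FISH probe signals; band-span extents are used only as a fallback when
neither exists, because published per-case intervals are probe/array
anchored and coarse band edges would otherwise overrule finer evidence (an
ish `q12.1` annotation does not widen an array result ending inside q12.1).
Probe polarity depends on case type: on a supernumerary marker any positive
signal demonstrates gain, while on an intrachromosomal duplication karyotype
a single `+` is the normal two-copy signal and only `++` demonstrates gain.
The centromeric D11Z1 probe is registered with the operational acen span
51,600,000–55,700,000 (printed-coordinate convention); a case whose resolved
extent does not reach beyond that span demonstrates no euchromatic gain and is
uninformative for span inference. Negative probe calls act as validators: an
extent overlapping a negative probe's span attaches a consistency warning but
is not truncated. Intervals published only in other builds (hg18) are flagged
needs-conversion and never used directly; the fixtures carry the published
GRCh37 conversions instead (no liftover is performed).

## Parser

The karyotype grammar is a deliberately permissive subset of ISCN 2020
implemented as a token scanner: clone stanzas (with cell counts, percentages,
ranges, and `[?]` unknowns), marker shape calls (`min`, `r`, `inv dup`,
including `min or r`), band spans with unicode or ASCII arrows and tolerated
`::` ring junctions, probe panels, `arr[build]` stanzas with thousands
separators (including the occasional `.` typo), and `mat`/`pat`/`dn`
inheritance tokens. Anything outside the grammar degrades to a preserved
remark, never a crash, because real case tables contain free-text rows. When
a case lists several shapes, the predominant shape is that of the clone with
the largest cell count, falling back to first-listed — cohort tables report
one shape per case without stating their rule, so this is the package's own
tie-break. A case is mosaic iff a marker-free clone coexists or the ISCN
`mos` designator is present (multi-marker carriers can be mosaic per marker
without any fully marker-free clone).

## Statistics and phenotype table

Percentages round half-up to one decimal (5/57 → 8.8%), with denominators
recorded alongside. Shape percentages use the number of shape-reported cases
(43 on the packaged cohort) as denominator; the curated counts give
48.8/46.5/4.7% for min/r/inv dup, within two points of the published rounded
values, which are non-integral on that denominator and therefore not exactly
reproducible. The male:female ratio is reported as raw counts plus the
male/female quotient. The phenotype table uses a closed nine-sign vocabulary;
a case contributes to every matching sign row but once per arm in the column
totals; a curated arm assignment overrides the coordinate-derived one with a
logged note (some published assignments rest on evidence that is not
coordinate-resolvable), and contributors whose cohort-level clinical status
is unresolved are flagged in the matrix notes rather than dropped.

## Synthetic cohorts

The generator emulates the statistical structure the inference assumes:
every simulated marker contains the centromere anchor and reaches an
exponentially distributed distance into each arm (default scale 5 Mb,
truncated at the arm, snapped to a 10 kb grid — producing the observed mix of
tiny heterochromatic and larger euchromatic markers without fitting
anything); a hidden insensitive span (default 48.0–60.5 Mb) surrounds the
anchor with hidden sensitive loci outside it (defaults at 44/40 Mb on p and
61.5/65 Mb on q); covering a locus makes a carrier abnormal with penetrance
(default 1.0), labels flip with a misclassification rate (default 0), and a
fraction of cases (default 0.39, mirroring the ~2/5 of published carriers
without usable clinical data) is made uninformative. All draws flow from one
seeded generator; identical seeds give byte-identical cohorts. The generator
also emits population evidence derived from its own truth: benign records
whose outer boundaries are the true span edges and pathogenic flanks at the
sensitive loci.

What the simulator does **not** emulate: UPD and imprinting effects,
tissue-specific mosaicism dynamics, neocentromeres, multi-chromosome complex
markers, and band-resolution-only evidence. Passing recovery tests therefore
show the inference is correct under the two-zone generative model, not that
real cohorts satisfy that model.

## Numerical and design choices

* Evidence-boundary ties: the coordinate closest to the refined span wins;
  equal coordinates deduplicate.
* Mosaic cases participate in inference regardless of mosaic level (mosaicism
  level shows no major phenotype influence in this marker class); a
  minimum-fraction filter exists but defaults to off (0.0).
* The cohort fixture stores case 10 with unknown clinical status, following
  the cohort-wide counts, while the informative-abnormal table carries it as
  abnormal per its own published assignment; the discrepancy is logged, not
  resolved. The default inference run uses the curated informative tables.
* A degenerate cohort (no informative normals) is an inference error at the
  span stage and a structured `failed` report in the recovery experiment.
* Problem sizes in the shipped tests: oracle equivalence uses 100 random
  cohorts on a 10 kb grid; recovery uses 20 seeds at n = 200 plus the
  50→200→800 growth series — sizes at which the binomial checks are stable
  and the whole suite runs in seconds.

## Known limitations

* The two-zone model admits no interior sensitive islands inside the
  insensitive span; a real interior dosage-sensitive gene would be missed by
  construction.
* Boundaries are deterministic extremes of observed intervals; no
  probabilistic or penetrance-weighted boundary estimation is attempted, so a
  single mislabeled carrier shifts a boundary (the recovery report surfaces
  such contamination against synthetic truth, but real cohorts have no truth
  flags).
* Windows are only as tight as the available pathogenic flanks; arms without
  pathogenic evidence yield open-ended windows.
* No gene-level annotation of the spans and no liftover between genome
  builds; inputs must be GRCh37.
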