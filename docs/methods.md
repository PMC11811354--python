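# Methods

## The screening statistic

On non-contrast CT, hepatic fat lowers liver attenuation. For each routed
study the analysis stage computes the unweighted arithmetic mean HU over the
liver and spleen masks, the spleen-hepatic attenuation difference
`SHAD = spleen_mean − liver_mean`, and the hepatic volume
(`voxel count × voxel volume / 1000` mL). The determinant for
moderate-to-severe steatosis is

```
present ⇔ liver_mean < 40 HU  or  SHAD > 10 HU
```

with strict inequalities on both sides; the report-template form
`liver − spleen < −10 HU` is the identical predicate (the code asserts the
equivalence in its test suite). Means are carried at full precision
internally and rounded only at report rendering. HU means are not
volume-weighted across slices: routing only admits uniform-thickness series,
which makes the weighted and unweighted means coincide, and the unweighted
choice is the simpler contract for plug-in segmenters.

The sign convention is fixed as spleen − liver, so both the screening cutoff
(`SHAD > 10`) and population means of either sign are representable.

## Routing

A study runs the algorithm iff

1. its CPT procedure code is in the configured set (default
   `{74176, 74150}`, the non-contrast abdominal CT codes). Codes are
   compared after stripping thousands separators, so `74,176 ≡ 74176`;
2. no instance of the candidate series carries a non-empty
   contrast-agent tag (an any-instance rule). A pixel-based contrast check
   is a documented extension point behind the same function; the metadata
   rule is the implemented behavior;
3. the series is axial within tolerance (|z-component of the slice normal|
   ≥ 1 − 0.01), its slice-thickness tag is uniform (exactly one distinct
   value — no tolerance, since tags are exact on both scanners and
   phantoms), and that thickness lies in the inclusive range [1, 5] mm. The
   range is configurable; thin sub-millimeter reconstructions are excluded
   by default to bound compute.

Among passing series the one with the **largest** slice thickness wins
(fewest slices, least compute), ties broken by lowest instance number then
lexicographic series UID. The selection policy is isolated in one function
so a different trade-off can be swapped in. The decision is a pure function
of its inputs, and its invariant — eligible ⇔ a series selected ⇔ no
rejection reasons — is enforced at construction; per-series rejection detail
is carried separately so the funnel can count it even for eligible studies.

## Segmentation: plug-in contract and fallback

Production-quality liver/spleen segmentation is a deep-learning problem and
deliberately outside this package; the contract is a callable
`SeriesStack → (liver_mask, spleen_mask)` with disjoint in-grid boolean
masks. Two implementations ship:

- `masks-on-disk`: loads externally supplied co-registered label volumes;
- `fallback`: thresholds to a soft-tissue window (default [−20, 200] HU),
  labels 3-D connected components, drops components below 20 mL, and calls
  the largest component liver and the next largest spleen.

The fallback exists so the pipeline is exercisable end to end with no model;
it is **not clinically valid**, and its size heuristic demonstrably
mislabels anatomy where the spleen outgrows the liver (a test documents
this). Segmentation failure (fewer than two qualifying components) marks the
study failed with no partial exports.

## The synthetic phantom

Each phantom is a small 3-D HU volume — default grid 10×64×64 at
3×5×5 mm spacing — containing an elliptical body outline per slice
(air −1000 HU outside), a subcutaneous fat ring (−100 HU), a
visceral-fat-like interior (−75 HU), and two non-overlapping ellipsoids:
"liver" (default 30 HU, ≈280 mL at this grid) and "spleen" (default 49 HU,
≈68 mL). Gaussian noise of configurable SD is added inside the body and the
result quantized to integer HU before DICOM write (slope 1, intercept
−1024, unsigned 16-bit), making fixtures bit-stable and zero-noise organ
means exact. UIDs are derived deterministically from the seed.

The interior is deliberately *below* the soft-tissue window rather than at a
soft-tissue value: with a 40–60 HU interior the liver, spleen and
surrounding tissue would merge into a single connected component under the
threshold fallback, and no classical labeller of this simplicity could
separate them. A fat-dominated visceral compartment keeps the organs as the
only soft-tissue components while remaining a recognizable abdominal layout.
`background_hu` stays configurable for callers using mask-based segmenters.

Six named scenarios (`steatotic`, `normal`, `nonuniform_thickness`,
`contrast_tagged`, `wrong_cpt`, `nonaxial`) each trigger exactly one routing
outcome; `steatotic` (liver 30 / spleen 49, CPT 74176) is the canonical
worked example and `normal` (liver 55 / spleen 50) sits on the other side of
both thresholds.

What the phantom does **not** emulate: anatomy (organ shape, position
variability, contact between organs), partial-volume effects at organ
boundaries, beam hardening and scanner noise texture, contrast-enhancement
pixels (only the metadata tag), or realistic organ volumes (the desk-scale
liver is ~280 mL against ~1500 mL in adults). Passing tests therefore
demonstrate the pipeline's plumbing, arithmetic and decision logic — not
segmentation accuracy or classification performance on clinical data.

## Reporting

CDE values are rounded to integer HU, half away from zero, and the printed
liver-minus-spleen difference is recomputed from the *rounded* liver and
spleen values so the rendered report is arithmetically self-consistent
(40.4 and 40.6 print as 40, 41 and −1, not 0). Unrounded values go to the
database. The DICOM-SR is a measurement-report pattern built directly on
pydicom: a root CONTAINER (DCM 126000), one NUM item per numeric CDE with
UCUM-coded units (HU as `[hnsf'U]`), one CODE item for the steatosis flag,
evidence references to the source instances, and the source study's UID.
Registry codes use the RADELEMENT coding scheme; values without a printed
registry code (hepatic volume) use clearly marked `LOCAL-` codes under a
private scheme.

QC overlays use the standard display transform (linear window, default
center 40 / width 400 HU abdominal window) and per-pixel alpha blending
(default α = 0.4; liver red, spleen blue; extra mask classes render
yellow/green if supplied). Overlap precedence is the fixed organ order
liver → spleen → extras. The render is exported as a Secondary Capture
series under the source study UID with per-instance provenance references.

## Orchestration

DICOM networking and HL7 triggering are emulated by a file drop-box: one
directory per study under the inbox, completion signalled by a
`study.complete` sentinel (mirroring the upstream "study complete" message)
or, where no upstream exists, by quiescence (no new instance for a
configured interval, default 2 s). Processing is single-worker, FIFO and
exactly-once: terminal states are persisted and a re-scan never reprocesses
a study; late-arriving instances are logged as warnings.

Exports are all-or-nothing per study: QC series then SR/report, each with up
to `max_retries` re-attempts under a configurable backoff schedule; if the
report leg fails permanently, already-landed QC files are rolled back so
nothing is half-exported, and the study lands in the
processed-but-not-exported category that the funnel counts. A retention
sweep deletes imaging data (inbox study + staging) once processing finished
more than `retention_days` ago (default 7 days); derived artifacts —
exported QC and SR files, database rows, event logs — are never swept, and
unprocessed studies are never deleted.

Every step appends `(study_uid, event, timestamp, detail)` to a JSON-lines
log. Timestamps within a study are clamped non-decreasing; instance-receipt
times come from file modification times (the drop-box analogue of network
receipt), processing events from an injectable clock.

## Metrics

Per study: `transfer = last_receipt − first_receipt`,
`processing = last_export_done − last_receipt`, `TAT = transfer +
processing`, in minutes at full precision (display rounds to one decimal,
so displayed components may differ from the displayed total by a rounding
step). The under-threshold fraction uses strict `<`. Studies without both
export events have no TAT and count in the failure category.

Funnel stages are defined operationally from the logs: `eligible_by_code` =
studies received (the drop-box stands in for the code-triggered transfer),
`transferred` = studies passing the CPT gate, then technical
rejection/selection, completion (analysis finished), and export (both
artifact sets landed). Stage percentages are stage-over-stage, rounded to
the nearest integer half away from zero; a zero denominator reports
undefined, never 0.

## Problem sizes and numerical choices

Defaults are chosen so a full phantom study processes in well under a
second: 10 slices of 64×64 voxels covers a 320 mm field of view at 5 mm
in-plane resolution, coarse but sufficient for organ-level mean-HU
statistics (the liver mask holds ~3700 voxels, so at noise SD 15 HU the
standard error of its mean is ~0.25 HU). The noisy-recovery check uses the
ground-truth masks at fixed N — the CLT bound 4σ/√N is only meaningful for
a fixed voxel count — while fallback-segmentation accuracy is measured
separately as Dice overlap (≥ 0.95 against truth). Orientation cosines must
be unit and orthogonal within 1e-3; duplicate slice positions are rejected
at 1e-6 mm; inter-slice spacing is the median of consecutive projected
position differences, and the thickness *tag* is kept separately because
routing checks the tag while geometry trusts positions. Only uncompressed
explicit-VR little-endian transfer syntax is written, and enhanced
multi-frame CT objects are rejected at read time.

## Known limitations

- The fallback segmenter is phantom-grade by design; all clinical claims
  require a real segmentation plug-in.
- The contrast check is metadata-only; an unlabelled contrast study would
  pass routing.
- The file drop-box emulation cannot reproduce network-level failure modes
  (batched transfer outages, association storms); the transport seam and
  retry machinery model them only at the level of per-export faults.
- Cohort-level clinical quantities (steatosis prevalence, population mean
  SHAD/attenuation/volume, the clinical TAT distribution) depend on a
  hospital's case mix and are out of scope at desk scale.
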