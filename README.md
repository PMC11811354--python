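# steatoscreen

A desk-scale clinical AI orchestrator for **opportunistic hepatic-steatosis
screening on non-contrast abdominal CT**, built for informatics researchers
and imaging-pipeline engineers who want to study, test, or extend an
end-to-end PACS-style AI deployment without a hospital behind it.

Fatty liver lowers hepatic attenuation on CT. Because abdominal CTs are
mostly acquired for unrelated indications, every non-contrast study is an
opportunity to screen: segment the liver and spleen, measure their mean
attenuation in Hounsfield units (HU), and apply the standard radiologic
determinant for moderate-to-severe steatosis

```
SHAD = mean(spleen HU) − mean(liver HU)
steatosis present  ⇔  mean(liver HU) < 40  or  SHAD > 10
```

(equivalently: liver − spleen < −10 HU). The package implements the whole
pipeline around that statistic:

- **`dicom_io`** — read single-frame CT DICOM instances, assemble
  geometry-checked series stacks in HU, write Secondary Capture series and
  re-readable derived objects;
- **`phantom`** — a synthetic abdominal-CT phantom generator: ellipsoidal
  liver/spleen with configurable mean HU and Gaussian noise, written as
  standards-compliant DICOM with controllable slice thickness, orientation,
  procedure code and contrast tagging, plus exact ground-truth masks;
- **`routing`** — eligibility rules: CPT procedure codes (74176/74150,
  thousands separators normalized), contrast-tag verification, axial
  orientation, slice-thickness uniformity and range, thickest-passing-series
  selection;
- **`steatosis`** — the analysis stage: a segmentation plug-in contract
  (with a phantom-grade classical fallback), organ mean attenuation, SHAD,
  hepatic volume, and the steatosis determinant;
- **`reporting`** — common-data-element (CDE) packaging (RDE1194, RDE1207,
  RDE1193, LIVF1), report-template filling, and DICOM-SR export/round-trip;
- **`overlay`** — radiologist-facing QC renders: windowed CT slices with
  transparent organ overlays, exported as an SC series in the same study;
- **`orchestrator`** — the runtime: file drop-box inbox, completion
  detection, exactly-once processing, export retry with rollback, an
  append-only results database, retention sweeps, JSONL event logs;
- **`metrics`** — turnaround-time decomposition (transfer + processing) and
  the staged eligibility funnel with rounded percentages.

## Worked example

```
mkdir demo && cd demo && mkdir inbox
steatoscreen generate-phantom --scenario steatotic --out inbox --seed 7
touch inbox/*/study.complete          # the "study complete" trigger
cat > config.toml <<'EOF'
inbox = "inbox"
pacs_outbox = "pacs"
report_outbox = "report"
work_dir = "work"
EOF
steatoscreen run --config config.toml
cat report/report.txt
```

prints the automatically populated report section:

```
ATTENUATION MEASUREMENTS:
Liver (30 HU) - Spleen (49 HU) = -19 HU
Hepatic steatosis: present
Threshold: liver < 40 HU or Liver-Spleen < -10 HU
(Hamer O, et al. RadioGraphics 2006)
```

The steatotic phantom draws its liver at 30 HU and spleen at 49 HU, so the
liver is both absolutely dark (< 40 HU) and 19 HU darker than the spleen
(SHAD = 19 > 10): steatosis is flagged. Alongside the text report the run
leaves a DICOM-SR carrying the same values as coded CDEs in `report/`, a
10-slice QC overlay series in `pacs/`, and an append-only database row with
the unrounded measurements in `work/database.csv`. `steatoscreen metrics
--config config.toml` then reports the funnel and turnaround-time summary
computed from the event logs:

```
funnel: FunnelCounts(eligible_by_code=1, transferred=1, rejected_technical=0,
                     selected=1, completed=1, exported=1)
TAT: mean transfer 0.0 min, mean processing 0.0 min, mean TAT 0.0 min,
     100.0% under 5 min, max 0.0 min
```

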