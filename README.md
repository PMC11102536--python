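# rotometry

Quantifies how accurately prescribed tooth rotations are achieved from 3D
dental arch models. Given pre-treatment (T0), planned (T1), and
post-treatment (T2) STL arch meshes with per-vertex tooth labels and two
landmarks per tooth, the pipeline:

1. superimposes each follow-up model onto T0 (3-point initial alignment of
   the two first-molar mesio-buccal cusp tips and the right central
   incisor's mesial incisal point, followed by a global iterative
   closest-point best fit capped at 50 iterations);
2. best-fits each segmented tooth surface individually to capture its own
   rigid motion and carries the T0 landmarks to the follow-up frame;
3. projects each tooth's landmark vector onto the occlusal plane (defined by
   the same three points on T0) and measures the signed angle between the T0
   and transferred vectors — the T0/T1 angle is the *prescribed* rotation,
   the T0/T2 angle the *achieved* rotation;
4. derives per-tooth outcomes — accuracy (achieved/prescribed x 100),
   performance (achieved − prescribed), its absolute-error frequency bins
   (<=1°, 1–2°, 2–4°, >4°), under/right/over-performance classes, and the 2°
   clinical exclusion cutoff — plus group summary tables;
5. runs the statistics layer: ICC and Dahlberg method error, Shapiro–Wilk
   gated paired t / Wilcoxon comparisons, OLS regression of accuracy on
   prescription, and noncentral-t power / sample-size analysis.

Because real scans are rarely shareable, `rotometry.synthetic_arch`
generates parabolic arches of seven crown types with known ground-truth
per-tooth rotations, whole-arch pose perturbations, and scanner-style vertex
jitter; every registration and measurement claim is tested against that
ground truth.

## Layout

| Module | Role |
| --- | --- |
| `rotometry.mesh_core` | mesh/label/landmark data model, STL read/write (ASCII + binary), tooth submesh extraction |
| `rotometry.synthetic_arch` | crown templates, arch generator, case emit/load |
| `rotometry.registration` | rigid transforms, 3-point alignment, global and per-tooth ICP, landmark transfer |
| `rotometry.rotation_measure` | occlusal plane, vector projection, signed angles, case measurement |
| `rotometry.outcome_metrics` | accuracy/performance/FOPE/direction records and group summaries |
| `rotometry.stats_report` | ICC, Dahlberg, paired comparisons, regression, power, report CSVs |
| `rotometry.pipeline` / `rotometry.cli` | reproducible multi-stage runs and the `rotometry` command |

## CLI

```bash
# full seeded run: simulate -> measure -> metrics -> analyze
rotometry run --seed 1 --out run/ --cases 5

# individual stages
rotometry simulate --seed 1 --out run/ --cases 5
rotometry measure  --seed 1 --out run/
rotometry metrics  --measurements run/measurements.csv --cutoff 2 --out run/metrics
rotometry analyze  --records run/metrics/records.csv --out run/report --alpha 0.05

# superimpose two arbitrary STL models
rotometry align --fixed t0.stl --moving t1.stl --init-landmarks lm.json --max-iter 50
```

A YAML config (`rotometry run --config cfg.yaml`) can override the
generator, registration, cutoff, and alpha settings; see
`rotometry.pipeline.RunConfig`.

## Notes

- Units are millimetres and degrees throughout; angles are signed so that a
  positive prescribed rotation defines the reference direction and a
  negative achieved value means the tooth rotated opposite to plan.
- STL carries no labels, so tooth labels and landmarks travel in sidecar
  JSON files next to each mesh (see `rotometry.synthetic_arch.emit_case`).
- All randomness is driven by explicit seeds; identical configs produce
  byte-identical artifacts.
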