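# gingimetry

Digital assessment of gingival recession coverage from superimposed
pre-/post-operative 3D dental-cast scans.

## The problem

After surgical root coverage (e.g. a coronally advanced tunnel with a soft
tissue graft), the outcome is classically quantified relative to the
cemento-enamel junction (CEJ): recession depth, mean root coverage (mRC) and
complete root coverage (cRC) all take the CEJ as the reference line.  The CEJ
is, however, an unreliable landmark — it is clinically undetectable in a
majority of cases, and on digitized casts the colour contrast needed to see
it is gone entirely.  A digital workflow that superimposes the pre-operative
and follow-up cast scans can instead measure the change directly between the
two gingival margins, with no CEJ involved.

`gingimetry` implements that workflow for pairs of STL cast scans plus
per-tooth landmark annotations:

1. **Registration** — rigid superimposition of the post-operative mesh onto
   the pre-operative one: principal-axis coarse alignment over the full arch,
   then point-to-plane ICP refined on tooth (crown) surfaces only, since the
   gingiva changed between timepoints.  Staged correspondence rejection
   (1.0 mm shrinking to 0.2 mm) and a final exact point-to-surface stage give
   sub-micron recovery on clean data.
2. **Measurement** — per annotated tooth:
   * recession depth `RD = (x_CEJ − x_margin)·â` along the tooth axis `â`
     (CEJ-dependent, kept for comparability),
   * `mRC = 100·(RD_pre − RD_post)/RD_pre` and the cohort cRC percentage,
   * **recession reduction** — the distance between the deepest points of the
     pre- and post-operative gingival margins in the common frame, signed by
     its axial component (CEJ-independent),
   * **gingival thickness gain** — signed buccal surface deviation sampled on
     the mid-tooth sagittal plane at 1 mm steps up to ±3 mm around the
     recession apex, with a single-point apex fallback when impression
     artifacts invalidate part of the grid.
3. **Statistics** — mixed-model factor comparisons (recession type, jaw,
   tooth type) with a patient random intercept and Scheffé-corrected pairwise
   contrasts; ICC(2,1) rater/replicate agreement with F-based CIs; and the
   non-inferiority sample-size formula
   `n = ⌈((z_{1−α/2} + z_{power})·σ/δ)²⌉` (87 % reference, 10-point margin,
   σ = 25, 90 % power, α = 5 % → 66 teeth).
4. **Synthetic data** — a parametric arch generator (teeth as smooth crown
   bulges on a gingival wall along a circular arc) with known per-tooth
   recession depths, coverage fractions, thickness gains, rigid misalignment,
   scanner noise and papilla artifacts.  It provides closed-form ground truth
   for every stage and is the basis of the test suite.

## Worked example

```python
import numpy as np
from gingimetry import (ArchParams, generate_arch_pair, register, assess_case,
                        mean_root_coverage, complete_root_coverage)

params = ArchParams(n_teeth=8, jaw="mandible", seed=42)
pre, post, annotations, truth = generate_arch_pair(params)
reg = register(post, pre, annotations)
print(f"registration: rms residual {reg.rms_residual:.4f} mm, "
      f"{reg.iterations} iterations")

records = assess_case(pre, post, annotations, reg)
mrc = mean_root_coverage(records)
crc = complete_root_coverage(records)
print(f"mean root coverage: {mrc.mean:.2f} +/- {mrc.sd:.2f} %")
print(f"complete root coverage: {crc:.2f} %")
for r in records[:3]:
    t = truth.by_id(r.tooth_id)
    print(f"{r.tooth_id}: depth pre {r.recession_depth_pre:.2f} mm, "
          f"reduction {r.recession_reduction:.2f} mm "
          f"(truth {t.true_reduction:.2f}), "
          f"thickness gain {r.thickness_gain:.2f} mm [{r.measurement_mode}]")
```

prints

```
registration: rms residual 0.0102 mm, 8 iterations
mean root coverage: 49.10 +/- 39.02 %
complete root coverage: 0.00 %
T01: depth pre 0.69 mm, reduction 0.69 mm (truth 0.69), thickness gain 0.10 mm [full_profile]
T02: depth pre 2.95 mm, reduction 0.85 mm (truth 0.85), thickness gain 0.22 mm [full_profile]
T03: depth pre 1.07 mm, reduction 0.99 mm (truth 0.99), thickness gain 0.27 mm [full_profile]
```

The registration residual sits at the simulated scanner-noise floor
(0.01 mm); the measured per-tooth reductions match the generator's drawn
values to well under a hundredth of a millimetre; in this 8-tooth draw no
post-operative margin reached the CEJ, hence a cRC of 0 %.

## Command line

```sh
gingimetry simulate --out case --n-teeth 8 --seed 42   # synthetic cast pair
gingimetry register --pre pre.stl --post post.stl \
    --annotations annotations.yaml --out transform.txt
gingimetry assess --pre pre.stl --post post.stl \
    --annotations annotations.yaml --transform transform.txt --out records.csv
gingimetry stats --records records.csv --out report.json
gingimetry samplesize                                  # planning figure
gingimetry run --config config.yaml                    # full pipeline
```

The annotation file is YAML with one record per tooth:

```yaml
teeth:
  - tooth_id: T01
    jaw: mandible               # or maxilla
    tooth_type: incisor         # incisor | canine | premolar | molar
    recession_type: RT1         # RT1 | RT2
    coronal_axis: [0, 0, 1]     # unit vector, crown-ward
    buccal_normal: [1, 0, 0]    # unit vector, out of the buccal surface
    margin_pre:  [[24.9, 0.1, -1.5], ...]   # gingival margin, pre-op frame
    margin_post: [[25.1, 0.3, -0.6], ...]   # gingival margin, post-op frame
    cej:         [[24.9, 0.1,  0.0], ...]   # optional; omit if not visible
    artifact_flag: false
```

When `cej` is omitted the CEJ-dependent metrics are flagged unavailable for
that tooth and it is excluded from mRC/cRC; the CEJ-independent metrics are
unaffected.  All coordinates are millimetres.

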