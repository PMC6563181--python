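# sternomet

Automatic sternal osteometry from 2D projection images.

In forensic anthropology the sternum is a well-preserved, sexually
dimorphic bone: standard measurements of its two large segments support
sex estimation when skulls or pelves are missing. Taking those
measurements by hand on CT-derived projections is slow and
observer-dependent. `sternomet` automates the whole chain for researchers
working with projected multi-slice CT images: it segments the manubrium
and sternal-body silhouettes, locates the anatomical landmarks, computes
the five standard measurements and three indices, classifies sex with
published discriminant functions (or refits new ones), and quantifies
manual-vs-automatic agreement. A synthetic phantom generator with exactly
known ground truth makes every stage testable without patient data.

## Measurements, indices, discriminant scores

Five lengths (cm): manubrium length **M** and width **MW**; sternal body
length **B** and widths **CSW1**, **CSW2** at the costal-notch 2/3 and 4/5
midpoint levels. Three indices: sternal index `SI = 100·M/B`, sternal
area `SA = (M+B)(MW+CSW1+CSW2)/3` (cm²), combined length `CL = M+B`.

Sex is estimated by linear discriminant scores `w·x + c` against a
sectioning point (above → male, below → female). Nine published functions
ship as a data resource — for example the best three-variable function
`0.965·MW + 0.712·B + 1.793·CSW1 − 17.123` with sectioning point −0.183 —
and two-group Fisher discriminants can be refit on labeled tables with
leave-one-out validation.

## Worked example

Render a corrupted sternal-body phantom, measure it automatically, and
classify the combined subject:

```python
from sternomet import (render_phantom, corrupt_image, CorruptionSpec,
                       measure_image, compute_indices,
                       builtin_functions, classify_sex)
from sternomet.osteometry import MeasurementRecord

image, truth = render_phantom({"B": 9.46, "CSW1": 2.65, "CSW2": 3.12},
                              spacing=0.05, kind="corpus", seed=1)
image = corrupt_image(image, truth, CorruptionSpec(seed=1))   # noise, breaks, distractors
rec = measure_image(image)
print({k: round(v, 3) for k, v in rec.values().items()})
# {'B': 9.444, 'CSW1': 2.649, 'CSW2': 3.085}

man_image, _ = render_phantom({"M": 5.23, "MW": 5.63}, 0.05, "manubrium", seed=2)
man = measure_image(man_image)
full = MeasurementRecord(subject_id="demo", M=man.M, MW=man.MW,
                         B=rec.B, CSW1=rec.CSW1, CSW2=rec.CSW2)
idx = compute_indices(full)
print(round(idx.SI, 2), round(idx.SA, 2), round(idx.CL, 2))
# 55.86 55.89 14.72

vals = {**full.values(), "SI": idx.SI, "SA": idx.SA, "CL": idx.CL}
for f in builtin_functions():
    if f.name in ("mw_b_csw1", "b", "sa"):
        print(f.name, classify_sex(f, vals))
# mw_b_csw1 female
# b female
# sa female
```

The automatic B of 9.444 cm sits 0.016 cm (a third of a pixel at
0.05 cm/px) from the phantom's true 9.46 cm despite the injected noise and
border breaks; the measurements fall on the female side of all three
sectioning points, as expected for values at the pooled population means.

The same workflow is available from the shell:

```bash
sternomet phantom generate --n 10 --seed 1 --out-dir phantoms/
sternomet run --images phantoms/ --out-dir results/ --spacing 0.05
sternomet fit --vars MW,B,CSW1 --in labeled.csv
sternomet agree --manual manual.csv --auto results/measurements.csv --out report.csv
```

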