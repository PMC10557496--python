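# drgrade

Explainable diabetic-retinopathy (DR) grading from typed lesion annotations.

Screening programs photograph the retina and grade each image on the
five-level scale 0 No DR, 1 Mild, 2 Moderate, 3 Severe, 4 Proliferate.
Deep detectors can find the lesions — hemorrhages (HE), hard exudates (EX),
soft exudates (SE), microaneurysms (AN), new vessels (NV) — but clinicians
need the *grade* to be transparent.  `drgrade` is the interpretable half of
such a system: it starts from the lesion polygons (clinician-drawn or
detector output in COCO-polygon JSON) and produces a severity grade with a
plain-language justification.

The grade rests on nine features per image. With `S_i^t` the shoelace area
of the *i*-th polygon of lesion type *t* and `S = (W/2)²π` the retinal area
(the retina modelled as a disk of radius half the cropped image width, which
stays correct for vertically clipped photographs):

    R_t = Σ_i S_i^t / S        for t ∈ {HE, EX, SE, NV}   (area ratios)
    N_t = #instances of t      for all five types         (counts)

Grading is a first-match scan over nine conjunctive threshold rules on
`R_SE, R_HE, N_SE, N_NV`, each carrying a confidence (the training-leaf
majority fraction).  The package also contains a from-scratch CART learner
(Gini, binary axis-aligned splits, deterministic tie-breaks) that re-derives
such rule sets with confidences from labeled feature tables, an interval-
arithmetic audit that proves the shipped rules mutually exclusive and
describes what they leave uncovered, a synthetic fundus/annotation generator
so every stage is testable without clinical data, and the classical fundus
preprocessing chain (crop-to-retina, resize, CLAHE, green channel,
augmentation).

## Worked example

```python
from drgrade import (FeatureVector, ImageAnnotation, LesionInstance, Polygon,
                     build_features, builtin_ruleset, classify, retina_area)

ann = ImageAnnotation("patient_042", width=1024, height=1024, instances=[
    LesionInstance("SE", Polygon([(300, 300), (500, 310), (520, 490), (310, 480)])),
    LesionInstance("HE", Polygon([(600, 200), (680, 210), (670, 290), (605, 285)])),
    LesionInstance("HE", Polygon([(150, 600), (230, 610), (220, 700)])),
    LesionInstance("AN", Polygon([(700, 700), (704, 700), (702, 704)])),
])
fv = build_features(ann, retina_area(ann.width))
print({k: round(v, 5) for k, v in fv.as_dict().items()})
res = classify(fv, builtin_ruleset())
print(res.severity, res.label, res.confidence)
print(res.explanation)
```

prints

```
{'R_HE': 0.01172, 'R_EX': 0.0, 'R_SE': 0.04462, 'R_NV': 0.0,
 'N_HE': 2, 'N_EX': 0, 'N_SE': 1, 'N_AN': 1, 'N_NV': 0}
1 Mild DR 99.396
If the ratio of soft exudate lesions is less than or equal 18% and the ratio
of hemorrhage lesions is less than or equal 5.2% and the number of soft
exudate lesions is between 1 and 15 and the ratio of soft exudate lesions is
less than or equal 11.1%, the severity is mild.
```

That is: one soft exudate covering 4.5 % of the retinal disk and two
hemorrhages covering 1.2 % land in the Mild-DR rule, whose training leaf was
99.4 % pure.

The same flow is available from the shell:

```bash
drgrade synth --out ds --n-per-class 10 --seed 1     # synthetic dataset
drgrade pipeline --annotations ds/annotations.json --out-dir out
drgrade train-cart --features ds/features.csv --out-rules rules.json
drgrade audit-rules
drgrade explain --rule-id moderate_he
```

See `docs/methods.md` for the model, its assumptions, the synthetic-data
design and known limitations.

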