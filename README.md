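# nucsize

Nuclear-size morphometry and majority-vote classification of lymphoma
histology tiles.

Nuclear size of neoplastic lymphocytes — small, intermediate or large — is a
key criterion for subtyping lymphoma. `nucsize` takes the *output* of any
nucleus segmentation model (a binary or instance mask of a 1024×1024 tile,
typically at 0.25 µm/pixel) and turns it into an interpretable image-level
size classification:

1. **Label** — binary masks are split into objects by 8-connected component
   labeling; instance masks are used as-is.
2. **Measure** — for every object k with pixel area A: the convex-hull area
   A_hull, the maximum border-pixel distance F (a Feret diameter), the
   two-ratio circularity

   c = ½ · ( A / A_hull + A / (π (F/2)²) ),

   and the equivalent circular diameter d = 2√(A/π) · s, where s is the
   pixel size in µm.
3. **Filter** — objects below 1 µm² or with c ≤ 0.5 are excluded (with a
   per-object reason and an overall dropout rate); merged or fragmentary
   detections are removed rather than repaired.
4. **Classify** — each kept nucleus is assigned a class from its size ratio
   ρ = d / r_ref against the species reference diameter r_ref (mean diameter
   of small non-neoplastic lymphocytes: 4.14 µm for dog, 4.17 µm for cat):
   small for ρ ∈ [1, 1.21), intermediate for ρ ∈ [1.21, 1.5), large for
   ρ ∈ [1.5, 2.24]; ratios outside [1, 2.24] are excluded as implausible.
5. **Vote** — the image class is the majority class over nuclei, with ties
   broken toward the larger class and flagged.

The four class thresholds are themselves obtainable by the included
brute-force grid search: every strictly ordered threshold quadruple on a
discretized grid is scored by the macro-averaged F1 of the per-image
majority classifications against expert consensus labels. The package also
provides segmentation quality metrics (Dice coefficient, IoU-based object
matching with precision/recall/F1, confusion matrices) and a seeded
synthetic scene generator so the entire pipeline is testable without slide
data.

## Worked example

```python
from nucsize import GeneratorConfig, generate_scene, run_workflow

scene = generate_scene(GeneratorConfig(n_objects=60, class_mix=(0, 0, 1), seed=21))
report = run_workflow(scene.mask, is_binary=False)
print(report.majority_class.value,
      dict((k.value, v) for k, v in report.class_counts.items()),
      f"dropout={report.dropout_rate:.2f}")
```

prints

```
large {'small': 0, 'intermediate': 0, 'large': 60} dropout=0.00
```

— a synthetic tile of 60 large-band nuclei (equivalent diameters between
1.5×4.14 µm and 2.24×4.14 µm) in which every object passes the shape filter
(dropout 0), all 60 vote "large", and the image is classified large.

The same pipeline is available from a shell:

```sh
nucsize generate --seed 21 --n-objects 60 --out scene/
nucsize classify scene/mask.png --overlays --out reports/
nucsize evaluate --pred scene/mask.png --truth scene/mask.png --out metrics.json
```

`classify` writes a JSON report per tile (per-nucleus diameters, ratios and
classes, exclusions with reasons, class distribution, majority class), a
per-nucleus CSV, and optional audit overlays (small = red, intermediate =
yellow, large = white; filtered objects shown in red on a separate panel).

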