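# drfvt — sketch-based silhouette retrieval with Fourier outline descriptors

`drfvt` retrieves labelled model views from a freehand sketch of a shape's
outline. It is aimed at view-based 3D-model retrieval settings — e.g. a
clinician sketching an organ silhouette to find matching anatomical models
— where the database side consists of 2D projection-view silhouettes and
the query is a rough, noisy drawing. The method combines **dimensionality
reduction (DR)** of Fourier outline descriptors with a **feature vector
transformation (FVT)** that makes the signature robust to noise; the
combination is called **DRFVT**.

## Method

1. **Outline tracing.** The closed outer boundary of a binary silhouette
   is traced with an eight-direction adaptive walk and parameterized as a
   complex periodic signal *z*<sub>*l*</sub> = *x*<sub>*l*</sub> +
   i·*y*<sub>*l*</sub>, resampled to *N* uniform arc-length points
   (default *N* = 256).
2. **Spectral encoding.** The DFT
   *Z*<sub>*m*</sub> = Σ<sub>*l*</sub> *z*<sub>*l*</sub>
   e<sup>−i2π*lm*/*N*</sup>, *m* = −*N*/2 … *N*/2−1, is normalized for
   translation (*Ẑ*<sub>0</sub> = 0), scale
   (*R̂*<sub>*m*</sub> = *R*<sub>*m*</sub>/*R*<sub>1</sub>), and jointly
   for rotation and starting point
   (*θ̂*<sub>*m*</sub> = *θ*<sub>*m*</sub> −
   (*θ*<sub>−1</sub>+*θ*<sub>1</sub>)/2 +
   *m*(*θ*<sub>−1</sub>−*θ*<sub>1</sub>)/2).
3. **Dimensionality reduction.** Only the *M* ≪ *N* coefficients nearest
   frequency zero are kept (default *M* = 32), with *M* selectable from
   the retained-energy curve *E*(*M*)/*E*(*N*),
   *E*(*M*) = Σ<sub>*m*=−*M*/2, *m*≠0</sub><sup>*M*/2−1</sup>
   |*Z*<sub>*m*</sub>|².
4. **Radial feature + FVT.** The inverse DFT of the truncated descriptor
   gives *M* canonical outline points; their distances
   *r*<sub>*t*</sub> to the centroid form the feature vector
   *R* = (*r*<sub>1</sub> … *r*<sub>*M*</sub>). The FVT cyclically
   rotates *R* to start at its minimum element, re-anchoring the vector
   when noise disturbs the start-point normalization.
5. **Matching.** Models are ranked by the Euclidean distance
   *D*(*X*, *Y*) = √Σ(*x*<sub>*i*</sub>−*y*<sub>*i*</sub>)², taking the
   minimum over a model's views.

A curvature baseline (**MAXC** — keep the *M* boundary points of highest
discrete curvature instead of the low-frequency content) and a
precision/recall harness (11-point interpolated curves, mean average
precision) support method comparisons. A synthetic generator produces
labelled organ-like silhouette benchmarks (harmonic-signature categories,
rotation/jitter/widen/cut view distortions) so everything runs without
external data.

## Worked example

```bash
drfvt synth --categories 3 --models 2 --views 2 --seed 3 --out bench
drfvt index --manifest bench/manifest.csv --out index.json --m 32
drfvt query --index index.json --image bench/body_00_v0.png --top-k 3
```

prints

```
indexed 6 models (12 views) -> index.json
  1  body_00               0.000000
  2  body_01               0.007553
  3  heart_00              0.012468
```

The queried image is itself indexed, so its model ranks first at distance
exactly 0; the next match is the other model of the same `body` category
(distance 0.0076 in normalized descriptor units, i.e. nearly the same
outline up to position/size/orientation/start), ahead of the nearest
other-category model. The four-way ablation on the same benchmark:

```bash
drfvt compare --manifest bench/manifest.csv --methods DRFVT,MAXC --out-json map.json
```

```
DRFVT       MAP = 1.0000
MAXC        MAP = 0.8667
```

Mean average precision (MAP) of 1.0 means every same-category model
outranks every other-category model for all 6 queries; the curvature
baseline misorders some.

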