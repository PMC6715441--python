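# raftsense

Label-free sensing, cytometry and splitting of adherent cell colonies on
**quad microraft arrays** — the full computational loop, from bright-field
z-stacks to an ordered, feedback-controlled release plan.

## The problem

Human iPSCs (and other adherent lines) grown on microraft arrays can be
split without enzymes or labels by mechanically ejecting individual
200 × 200 µm cell carriers ("microrafts") — but only if software can *see*
unlabeled colonies on an optically busy, multiplanar array surface, track
every colony site over days of culture, and decide which raft of each 2×2
cluster ("quad") to eject. Plain bright-field images have far too little
contrast for that.

The trick this package implements: cell appearance changes strongly with
focus while the array substrate does not. Acquiring bright-field images at
several focal planes (±57 µm around focus) and projecting the **pixelwise
standard deviation along z** (SDP) lights up cells; subtracting a
pre-seeding **background** scan plane-by-plane first (the **B-SDP**)
removes the array's own texture:

```
B-SDP(x) = std_z [ S_z(x) − B_z(T(x)) ]
```

where `S_z`, `B_z` are flat-field-corrected signal/background planes and
`T` is a sub-pixel rigid registration (±0.5° rotation search, DFT-based
translation). The B-SDP is then top-hat filtered (2 × 33 µm rectangles at
0°/90°, combined by pixelwise minimum) to remove raft edges, local-entropy
filtered (14 µm disk) to fuse punctate per-cell signal into colony patches,
opened by reconstruction (40 µm disk), Otsu-thresholded, hole-filled,
contracted by 8 µm and majority-filtered into labeled colony masks.

Downstream, the package detects and indexes every quad on the array
(Otsu + morphology, centroid consolidation at 430 µm, piecewise-linear
interpolation of missing sites in 8 mm segments), measures per-raft
coverage (a raft is "covered" at ≥50%), classifies colonies as spanning
1–4 rafts, selects one release target per eligible quad (≥2 covered rafts;
the covered raft with least PDMS outgrowth), orders targets with a
Nearest-Neighbor tour, and drives a closed release loop (success at >80%
dislodgement, re-aim at the residual-material centroid, halt after 8
attempts, >70 µm centroid drift, or >1/3 of the raft outside its well).

Everything is testable without a microscope: the `synth` module renders
bright-field z-stacks of whole arrays — focus-invariant background texture,
focus-varying cell speckle and halo, illumination gradients, stage
misregistration, sensor noise, lattice distortion — with exact ground
truth.

## Worked example

```python
from raftsense import (random_scene, render_array_background,
                       render_signal_stack, run_pipeline, evaluate_mask)

spec = random_scene(seed=1)                 # 8x8 quads, ~15 colonies
background = render_array_background(spec)  # pre-seeding scan
signal, truth = render_signal_stack(spec)   # cell-laden scan + ground truth

mask, diag = run_pipeline(signal, background)
m = evaluate_mask(mask, truth.cell_mask)
print(f"colonies: {mask.n_colonies}")
print(f"sensitivity {m.sensitivity:.3f}  specificity {m.specificity:.3f}  "
      f"MCC {m.mcc:.3f}  SNR gain {diag['snr_gain']:.1f}x")
```

prints (seed 1):

```
colonies: 24
sensitivity 0.937  specificity 1.000  MCC 0.964  SNR gain 11.8x
```

i.e. on this scene the pipeline recovers 93.7% of true cell pixels, marks
essentially no false cell pixels, and the B-SDP carries ~12× the
signal-to-noise of the raw bright-field plane. The same loop continues to
grid indexing, coverage records and release planning; or run it from the
shell:

```bash
raftsense run-all --seed 1 --out out/     # simulate -> segment -> grid ->
                                          # cytometry -> plan -> release-sim
```

## Layout

| module | role |
| --- | --- |
| `raftsense.synth` | synthetic array/scene renderer + exact ground truth |
| `raftsense.preprocess` | flat-field correction, normalization, rigid registration |
| `raftsense.bsdp` | B-SDP enhancement and colony segmentation |
| `raftsense.grid` | quad detection, indexing, interpolation, tracking |
| `raftsense.cytometry` | coverage records, class histograms, metrics, growth fits |
| `raftsense.release` | target selection, NN ordering, release feedback loop |
| `raftsense.cli` | `raftsense` command-line entry point |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
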