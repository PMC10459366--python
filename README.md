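# mielapse

Motion-informed enhancement (MIE) and evaluation of small-insect
detections in time-lapse camera recordings.

## The problem

Camera traps for pollinator monitoring record still images of flowering
vegetation every 30 s over weeks. Insects such as honeybees are tiny
relative to the 1920 × 1080 frame, frequently occluded, and coloured
much like the scene around them, so single-image object detectors
struggle — yet between consecutive frames the insect is usually the
only thing that moves. This package implements a preprocessing and
evaluation toolkit for that setting, aimed at ecologists and
computer-vision practitioners who run detection pipelines over
long-term time-lapse recordings.

## The method

Three consecutive frames are reduced to blurred grayscale images
$B_{k-1}, B_k, B_{k+1}$ (BT.601 luma, 5 × 5 Gaussian). The per-pixel
three-frame motion likelihood is

$$L^3_k[i,j] = |B_k[i,j] - B_{k-1}[i,j]| + |B_{k+1}[i,j] - B_k[i,j]|$$

and the enhanced image $M$ re-maps the colour channels of the centre
frame:

$$M_r = L^3_k \text{ (clamped to 255)}, \qquad M_g = I_g, \qquad
M_b = \tfrac{1}{2}(I_r + I_b).$$

The result is still an ordinary RGB image — green vegetation stays
green, flower colours fold into blue, and anything that moved glows
red — so any off-the-shelf detector can consume it unchanged.

Around that core the package provides:

* **sequence_io** — timestamped sequence loading, nightly-gap run
  segmentation, YOLO label and detection-CSV round-trips;
* **detection** — a non-learned motion-blob baseline detector (threshold
  + morphology + connected components on $M_r$) and an adapter for
  external CNN detector outputs;
* **evaluation** — greedy one-to-one IoU matching (IoU > 0.25 by
  default), precision/recall/F1, per-site metrics with macro and micro
  averaging, and all-point interpolated average precision;
* **abundance** — the two-minute same-position duplicate filter and
  raw/filtered abundance time series;
* **synthetic** — a seeded generator of vegetation scenes with moving
  insect blobs and exact ground truth, so the full pipeline is testable
  without any dataset download.

## Worked example

```python
from mielapse import (SceneConfig, BackgroundConfig, generate_benchmark,
                      run_baseline_on_sites)

config = SceneConfig(n_frames=60, seed=0,
                     background=BackgroundConfig(illumination_jitter=0.0, sway_px=0.0))
sites = generate_benchmark(config, n_sites=3)
result = run_baseline_on_sites(sites)

for s in result.sites:
    print(f"{s.site_id}: TP={s.tp} FP={s.fp} FN={s.fn} "
          f"P={s.precision:.3f} R={s.recall:.3f} F1={s.f1:.3f}")
agg = result.aggregate
print(f"micro: P={agg.micro_precision:.3f} R={agg.micro_recall:.3f} F1={agg.micro_f1:.3f}")
print(f"macro: P={agg.macro_precision:.3f} R={agg.macro_recall:.3f} F1={agg.macro_f1:.3f}")
```

Output:

```
SYN-0: TP=2 FP=0 FN=0 P=1.000 R=1.000 F1=1.000
SYN-1: TP=0 FP=0 FN=0 P=0.000 R=0.000 F1=0.000
SYN-2: TP=5 FP=0 FN=0 P=1.000 R=1.000 F1=1.000
micro: P=1.000 R=1.000 F1=1.000
macro: P=0.667 R=0.667 F1=0.667
```

Three synthetic camera sites are generated with insect prevalences
drawn from 1–15 % of frames; the blob baseline run on the
motion-enhanced frames recovers every planted insect here. Site SYN-1
drew a prevalence so low that no insect appears in its 60 frames; by
the zero-denominator convention its metrics are 0, which is why the
macro average (unweighted mean over sites) sits below the micro
average (pooled TP/FP/FN counts).

The same stages are scriptable from the shell:

```bash
mielapse simulate --out bench --sites 7 --frames 50 --seed 1
mielapse detect --input bench/SYN-0/images --output dets.csv
mielapse evaluate --detections dets.csv --manifest bench/manifest.csv
mielapse abundance --detections dets.csv --out abundance.csv
```

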