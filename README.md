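# pcmquant

Quantification of pericentriolar-material (PCM) disassembly from
fluorescence time-lapse movies of *C. elegans* embryos — and a
ground-truthed synthetic embryo simulator that makes the whole analysis
testable without raw microscopy data.

## The problem

At mitotic exit the micron-scale PCM that surrounds each centriole is
rapidly dismantled. Live imaging of a GFP-labelled PCM scaffold protein
shows the PCM mass growing after nuclear envelope breakdown (NEBD), peaking
around anaphase (~275 s post-NEBD), then decaying until it is undetectable;
depleting the relevant phosphatase or cortical pulling forces slows the
decay and can leave ~25% of the peak mass persisting into the next cell
cycle. Turning such movies into those numbers requires a careful per-frame
measurement pipeline, which this package implements as a reusable,
falsifiable library for cell biologists quantifying spot-like organelles in
time-lapse data.

## The measurement

For each centrosome movie (after SUM-projecting the z-stack, splitting the
embryo into anterior/posterior halves, and discarding pre-NEBD frames):

1. **Seed** — on the first frame, Gaussian-blur (σ = 1 px) and take the
   maximum-intensity pixel as the centrosome centre.
2. **Background** — mean μ_bg and standard deviation σ_bg over the annulus
   of radii 7–10 px around the seed.
3. **Threshold** — T = μ_bg + 3·σ_bg, computed once on the first frame and
   applied to every frame.
4. **ROI and mass** — the seed-connected component of pixels above T; the
   integrated signal intensity (the PCM-mass proxy) is

   M = (mean_ROI − T) · area_ROI = Σ_ROI (pixel − T).

For unresolvable centrosome pairs a *merged* mode uses an enlarged annulus
and divides every mass by two. Downstream, curves are normalized to their
own maximum, aligned at NEBD or at disassembly onset (the smoothed-curve
peak), and summarized as a disassembly rate (least-squares slope from onset
to half-maximum), percent rate reduction versus a reference condition, and
a persistence fraction (trailing-window median of normalized mass).

The simulator renders embryos with two diffraction-blurred centrosome foci
whose true mass follows logistic growth to a peak, then exponential decay
to a residual plateau, under a Poisson + Gaussian camera model — with
per-frame ground truth, so every estimator is checked by parameter
recovery.

## Worked example

```python
from pcmquant.pipeline import quantify_simulated
from pcmquant.kinetics import PCMDisassemblyModel

curves = [
    quantify_simulated("wild_type", "anterior", rng_seed=s, n_frames=60)[0]
    for s in range(4)
]
print(PCMDisassemblyModel(curves, condition="wild_type").fit().summary())
```

```
PCM disassembly kinetics
================================================================
condition: wild_type    curves: 4

   curve condition  onset_s  rate_per_s  r_squared  persistence  n_frames
anterior wild_type      260   -0.007638     0.9775      0.01809        60
anterior wild_type      260   -0.007587     0.9753      0.01974        60
anterior wild_type      260   -0.007589     0.9758      0.01853        60
anterior wild_type      260   -0.007601     0.9772      0.01836        60

mean onset: 260 +/- 0 (95% CI) [s post-NEBD]
mean rate: -0.007604 +/- 2.32e-05 (95% CI) [norm. mass/s]
mean persistence: 0.01868 +/- 0.0007172 (95% CI) [fraction of peak]
```

Each row is one simulated embryo's anterior centrosome: disassembly onset
is detected at 260 s post-NEBD (the programmed peak is at 275 s; the
smoothed-argmax rule sits about one frame early on an asymmetric peak), the
normalized mass then falls at ~0.0076 per second, and essentially nothing
persists at the end of the movie — wild-type PCM disassembles completely.

The same objects work on real data: build a `MovieStack` from a TIFF +
sidecar JSON (`pcmquant.ingest.load_movie`), or run the CLI chain

```bash
pcmquant simulate --preset wild_type --seed 7 --frames 60 --out sim/
pcmquant ingest --tiff sim/wild_type.tif --meta sim/wild_type.json --out proj/
pcmquant quantify --tiff proj/anterior.tif --meta proj/anterior.json --out anterior.csv
pcmquant curves --inputs anterior.csv --anchor onset --out summary/
```

A second analysis mode (`pcmquant.ratio`) measures per-centrosome
two-channel antibody-signal ratios (phospho-state-specific / total
scaffold) over one ROI segmented on the total channel, normalizes them to
the interphase mean, and compares cell-cycle stages with Welch's t-test.

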