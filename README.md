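# bednettrack

Video tracking of low-contrast flying mosquitoes around human-baited bednets.

Nocturnal, host-seeking *Anopheles* mosquitoes are recorded at ~50 frames s⁻¹
against a bright, infrared-illuminated background (≈0.5 mm per pixel), where
they appear as small dark images of only a few greyscales contrast.  Through
bednet mesh the contrast falls to 1–2 greyscales — the same order as the
camera's temporal noise (≈1.84% of mean intensity) — which is what makes the
bednet region, exactly where mosquitoes interact with insecticide, the
hardest place to track them.  This package implements the segmentation and
tracking pipeline used for such recordings, the track-quality metrics used
to grade it, and a synthetic scene simulator that emulates the photometric
structure of the two recording rigs (retro-reflective screen vs backlit
Fresnel illumination) so the whole pipeline can be benchmarked against known
ground truth without any recordings.

It is aimed at researchers analysing insect flight video, or evaluating
imaging rigs for that purpose.

## Method

**Segmentation** (per frame *n*):

1. Signed difference image `D = frame(n−i) − frame(n)` (lag *i* = 5), so a
   dark mosquito produces a positive peak at its current position and a
   negative one at its old position.
2. Gaussian denoising of `D` with a normalised `ksize × ksize` kernel
   (default 15 × 15), `σ = 0.3·((ksize−1)·0.5 − 1) + 0.8` (σ = 2.6 px at 15).
3. The image is partitioned, from a mosquito-free reference frame, into a
   bright *background* region (≥ 40–60 greyscales), a darker *bednet* region
   and *occluded* areas.  Positive differences are thresholded at 3
   greyscales in the background region and 1 greyscale in the bednet region.
4. Suprathreshold pixels are dilated (5 px) to rejoin broken-up images, the
   union of both passes is labelled 8-connected, components outside an area
   window are removed, and difference-weighted sub-pixel centroids are kept.

**Tracking**: greedy nearest-neighbour linking frame to frame (gate 40 px
per frame step), tolerating a single missing position at a time; fragments
with fewer than five positions are discarded.  A second pass lengthens and
combines fragments across gaps of up to 15 frames, ranked by gap then by
straight-line extrapolation cost.

**Metrics**: with Δt the inter-frame time and Δt_k the time between
consecutive recorded positions, a track's potential positions and missed
positions are

    N_t    = Σ_{k=0}^{n−1} Int[Δt_k / Δt]        (Δt_0 ≔ Δt)
    N_Gaps = Σ_{k=0}^{n−1} Int[Δt_k / Δt − 1]

so that `n + N_Gaps = N_t`.  The headline figure is the detection
percentage `100 · Σn / ΣN_t`, reported overall and stratified into
across-net / outside-net regions, alongside gap-size statistics and mean
(uninterrupted) track lengths.

## Worked example

Run the pinned retro-reflective-screen benchmark scene, shortened to 600
frames (12 s of video):

```bash
bednettrack benchmark --mode rrs --seed 1 --n-frames 600
```

```
mode=rrs seed=1 frames=600
  detected positions in tracks: 5691
  number of tracks: 59
  mean gap size (frames) across net: 1.839
  ...
  detected mosquitoes across net (%): 89.735
  detected mosquitoes outside net (%): 92.881
  detected mosquitoes overall (%): 91.584
```

Ten simulated mosquitoes yield 59 tracks (tethered flights re-enter and
leave the scene's trackable regions repeatedly); 5,691 of their potential
positions were recovered.  Mean gaps under two frames and an overall
detection percentage above 90% are the signature of the RRS illumination
regime; running the same command with `--mode backlit` drops the overall
percentage below 70%, with markedly shorter uninterrupted track stretches.

The same pipeline runs on recorded footage (multi-page 8-bit TIFF or a
numbered PNG directory):

```bash
bednettrack run --config myrun.yaml --out-dir out/   # or: segment / track / metrics
```

producing `detections.csv`, `tracks.csv` and `metrics.json`, each stamped
with the configuration hash and seed.

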