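# slicetox

Quantification of trauma-induced injury in acute brain slices from
dual-channel two-photon imaging.

Cutting a living brain slice traumatizes its surface. In neonatal slices
expressing the Ca²⁺ indicator GCaMP6s and stained with propidium iodide
(PI), this injury shows up as three measurable populations: **PI⁺ cells**
(membrane-compromised, dead or dying), **GCaMP-filled neurons** (tonically
bright, Ca²⁺-overloaded, silent), and **colocalized puncta** (both at once).
All three concentrate near the cut surface and fall off with depth.
`slicetox` turns z-stacks and Ca²⁺ movies of such slices into the numbers
that describe this injury gradient, and ships a synthetic-data generator
with exact ground truth so every stage is testable without any microscope.

## What it computes

Given a dual-channel z-stack (green = GCaMP6s, red = PI; 0–300 µm at
2–3 µm steps):

1. **Preprocessing** — 8-bit conversion (joint scale across channels),
   median smoothing (disk radius 2), maximum-intensity projections over
   groups of five planes (10–15 µm sections), robust background
   subtraction per MIP.
2. **Detection** — binary mask at 5× the background SD, particle
   segmentation with size/circularity windows (PI⁺ 10–100 µm²,
   GCaMP-filled 20–200 µm², circularity 0.5–1).
3. **Bleed-through elimination** — about half the green signal leaks into
   the red detector, so bright green somata create false PI⁺ detections.
   The normalized excess ratio r = (R − G)/G is negative iff green
   dominates; detections with r below a Gaussian-derived threshold
   (mean − 1 SD of the true-positive ratio distribution, −0.4) are
   eliminated.
4. **Colocalization** — one-to-one centroid matching of red and green
   detections (≤ 10 µm in-plane, ≤ 1 MIP apart).
5. **Depth profiling** — counts per 30-µm bin, normalized to the slice
   total, fitted with y = A·exp(−z/τ). The decay constant τ (µm) is the
   headline injury statistic; cumulative summaries report e.g. the depth
   containing 75 % of cells.
6. **Ca²⁺ transients** — per-ROI neuropil-subtracted traces,
   ΔF/F₀ = (F_t − F₀)/F₀, MAD-threshold event detection, and per-event
   frequency, amplitude, AUC and FWHM; classification of GCaMP-filled
   (bright and silent) ROIs; 4×4 grid statistics relating local neuropil
   intensity to local PI⁺ density.

## Worked example

Run the full pipeline on the built-in baseline condition (`fig1`: τ_PI
41 µm, τ_filled 65 µm, τ_neuropil 131 µm, 50 % bleed-through, read noise
SD 4):

```sh
slicetox run --preset fig1 --seed 7 --out demo
```

The printed report (also `demo/report.json`) contains, among other stages:

```
"detect":       {"n_green": 70, "n_red_raw": 130}
"bleedthrough": {"n_eliminated": 57, "n_kept": 73}
"coloc":        {"n_pairs": 13}
"depthprofile": {"red": {"tau": 47.8, "r2": 0.966,
                          "frac_0_90": 0.904, "depth_75pct": 65.9, ...}}
```

Reading: 130 raw red detections include bleed-through ghosts of the 70
green somata; the ratio filter removes 57 of them, leaving 73 PI⁺
detections, 13 of which colocalize with a GCaMP-filled neuron. The
red-channel depth profile decays with fitted τ ≈ 48 µm (the kept reds mix
τ = 41 µm PI⁺ cells with τ = 65 µm colocalized ones), 90 % of them within
the top 90 µm, and 75 % above 66 µm depth.

Other entry points:

```sh
slicetox simulate --preset fig1 --seed 1 --out sim   # stacks + truth table
slicetox calcium --preset deep --seed 2              # movie transient metrics
slicetox profile --detections sim/truth.csv          # depth profile + tau of any table
slicetox run --config run.yaml                       # full control via YAML
```

The same functionality is available as a library (`slicetox.synthetic`,
`slicetox.prep`, `slicetox.detect`, `slicetox.bleedthrough`,
`slicetox.coloc`, `slicetox.depthprofile`, `slicetox.calcium`).

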