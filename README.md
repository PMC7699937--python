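# drtb — stomatal segmentation by Delaunay-Rayleigh threshold binarization

Stomata are the pores on a leaf's epidermis through which CO₂ enters and
water vapour leaves; their density and spacing are central quantities in
plant physiology, and counting them in light micrographs is tedious manual
work. Most automatic detectors rely on colour or shape. `drtb` instead
exploits a *spatial* property: stomatal centers are spread over the leaf
with near-regular spacing, so the Delaunay edge lengths of correctly
segmented centers follow a Rayleigh-like frequency distribution

&nbsp;&nbsp;&nbsp;&nbsp;ℛ(d | σ) = (d/σ²)·exp(−d²/2σ²),

which arises exactly as the nearest-neighbour law of a homogeneous Poisson
point process. The algorithm scans every binarization level *l* of a
preprocessed grey image F, extracts region centroids at each level, and
keeps the level whose Delaunay edge-length histogram p(d|l) is closest, in
root-mean-square deviation, to the best-fitting Rayleigh:

&nbsp;&nbsp;&nbsp;&nbsp;l̂ = argmin_l min_σ RMSD(σ, l).

Per level the chain is: binarize (pixels > l) → 8-connected component
labeling → median-absolute-deviation area filter (MAD = 1.4826·median|r −
median r|, keep |r_i − median r|/MAD < 3) → first-moment centroids →
Delaunay triangulation → edge-length histogram → grid fit of σ. The
preprocessing that produces F is Perona-Malik anisotropic diffusion of the
red channel, mean-shift quantization of its intensities, and elementwise
(Hadamard) division of the image's HSV saturation channel by the result —
stomata retain high saturation and low red response relative to the
cuticle, so the ratio amplifies the split.

The package also ships the matching evaluation protocol (greedy one-to-one
center matching within a radius; precision PPV = TP/(TP+FP), recall
TPR = TP/(TP+FN)) and a seeded synthetic generator (Poisson or hard-core
point patterns, rendered stomata-like micrographs with ground truth) so
every stage is testable without any image download.

## Worked example

Generate a synthetic micrograph with 136 planted stomata, segment it, and
score the detections against the planted truth:

```
$ drtb synth --preset clean --seed 1 --outdir demo
clean: 136 planted stomata -> demo

$ drtb segment --input demo/image.tiff --config demo/config.yaml --outdir demo/out
optimal level 0.86 sigma 49.50 rmsd 0.00279 (136 centroids)

$ drtb evaluate --pred demo/out/centroids.csv --truth demo/truth.csv \
      --radius 10 --out demo/metrics.json
radius 10 px: TP=136 FP=0 FN=0 PPV=1.0000 TPR=1.0000
```

`demo/config.yaml` (written by `synth` next to the image) holds the scan
grids matched to the synthetic scale — a σ search of 20–150 px and a
minimum region area of 30 px; see `docs/methods.md` for why.
The segment step reports the selected binarization level l̂ = 0.86, the
fitted Rayleigh parameter σ = 49.5 px (the characteristic stomatal spacing
scale of this render) and the residual RMSD between the edge-length
histogram and the fitted Rayleigh mass. All 136 planted centers are
recovered within 10 px with no false positives. `demo/out/` also contains
the per-level scan table (`scan.csv`), the binary mask at l̂ (`mask.png`)
and an overlay with centroid dots and fitted region ellipses
(`overlay.png`).

The same `segment`/`evaluate` commands run on real micrographs (PNG, TIFF
or JPEG, 8- or 16-bit); the config file exposes every preprocessing and
scan parameter (diffusion iterations and contrast, mean-shift bandwidth,
level and σ grids, histogram bin width, MAD cutoff, minimum region area,
polarity inversion).

## Library use

```python
import drtb

pp, rp = drtb.get_preset("clean", seed=1)
pts = drtb.sample_poisson_points(pp)          # ground-truth centers
img = drtb.render_stomata_image(pts, rp)      # RGB micrograph
f = drtb.preprocess_pipeline(img)             # grey image F in [0,1]
res = drtb.segment(f)                         # full threshold scan
print(res.best.level, res.best.sigma, len(res.centroids))
```

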