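# bloomsat

Detection and two-date change analysis of mass-flowering tree crowns in
high-resolution multispectral satellite imagery.

Some tropical canopy trees — *Tabebuia guayacan* in Panama is the archetype —
flower in brief, rain-triggered "big bang" episodes: the whole reproductive
population erupts in bright yellow blooms for about two days, in near-perfect
synchrony. A single satellite image timed to such an episode therefore
captures the entire flowering population at once, and comparing two episodes
years apart reveals which trees persisted, which fell or skipped an event,
and which recruits newly reached reproductive size. `bloomsat` implements
that analysis chain for 4-band (blue/green/red/NIR) reflectance imagery at
Quickbird-like ~2.4 m resolution, for ecologists and remote-sensing analysts
who want a fully automated, reproducible version of the workflow — plus a
synthetic scene generator with planted ground truth so every stage can be
validated without proprietary imagery.

## Method

1. **Pure-pixel extraction (one-class SVM).** Candidate flowering pixels
   (the brightest pixels in the flower-dominant green and red bands) train a
   one-class SVM with RBF kernel K(x, y) = exp(−γ‖x−y‖²), solving

       min_α ½ Σᵢⱼ αᵢαⱼK(xᵢ, xⱼ)   s.t.  0 ≤ αᵢ ≤ 1/(νl),  Σᵢαᵢ = 1

   with decision f(x) = Σᵢ αᵢK(xᵢ, x) − b; pixels with f ≥ 0 form a binary
   pure-pixel map. ν bounds the training outlier fraction; γ sets the kernel
   width. The **target endmember** t is the per-band mean of the flagged
   pixels.
2. **Spectral angle mapping (SAM).** θ = arccos(t·r / (|t||r|)) per pixel —
   a shape-only similarity, insensitive to illumination.
3. **Linear spectral unmixing (LSU).** Each pixel r_b = Σᵢ FᵢR_ib + E_b is
   decomposed by constrained least squares (fractions sum to one,
   non-negative) over the target plus background endmembers (vegetation,
   soil, water, man-made), giving the flower fractional abundance F.
4. **Region rule.** Pixels with F > 0.80 are pure flowering crown
   (Region A); pixels with 0.25 < F ≤ 0.80 *and* θ < 0.05 rad are crown-edge
   mixtures (Region B); everything else is background.
5. **Crown isolation.** ISODATA clustering (25 spectral classes) isolates
   the classes dominated by Region A/B pixels; 8-connected components of the
   selected pixels become centroid points; centroids within 5.0 m of one
   another are merged (transitively) into single crowns.
6. **Change detection.** Two dates' crown sets are matched one-to-one by
   greedy nearest pair within a 5.0 m tolerance: matched crowns are common
   trees, date-1-only crowns are lost, date-2-only crowns are new.

## Worked example

```python
import bloomsat as bs

params = bs.SceneParams(width=256, height=256, n_crowns=100, seed=5)
img1, img2, truth = bs.generate_scene_pair(params, shared_fraction=0.5)
report, set1, set2, manifests = bs.run_two_date(img1, img2)
print(report.summary())
```

prints

```
{'n_date1': 75, 'n_date2': 75, 'n_common': 50, 'n_lost': 25, 'n_new': 25, 'tolerance_m': 5.0}
```

The generator planted 100 crowns, 50 flowering on both dates and 25 on each
date only; the pipeline detected all 75 crowns per date and recovered the
common/lost/new partition exactly. The same run is available from the shell:

```bash
bloomsat simulate --out-dir sim --seed 5 --n-crowns 100 --shared-fraction 0.5
bloomsat run-all --image1 sim/scene_date1.tif --image2 sim/scene_date2.tif --out-dir out
```

A packaged 18-site comparison of satellite-detected crowns against
high-resolution aerial photography is also included:

```python
table = bs.load_aerial_comparison()
print(bs.match_rate(table, date=1))   # -> 88  (percent of first-date crowns re-found)
```

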