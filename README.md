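# mtjquant

Quantification pipeline for muscle structure and function in zebrafish
models of muscular dystrophy. Dystrophic embryos (e.g. *dag1* or *itga7*
morphants) degenerate because muscle fibers detach from the laminin-rich
basement membrane (BM) at the myotendinous junction (MTJ); treatments such
as NAD⁺ supplementation are assessed by how much they restore BM
organization, fiber attachment, and swimming performance. `mtjquant`
implements the measurement side of that assay suite:

* **2-D wavelet transform modulus maxima (2DWTMM)** analysis of
  fluorescence micrographs: multiscale Gaussian-derivative gradients,
  modulus-maxima detection and chaining, and a per-scale **anisotropy
  factor** `F(a) = (1/N)‖Σ_k (cos 2A_k, sin 2A_k)‖ ∈ [0, 1]` — the axial
  resultant length of the gradient directions `A_k` at the maxima. Parallel
  band edges give `F → 1`; isotropic texture gives `F → 0`. Higher `F`
  means a more organized BM.
* **Muscle-structure metrics**: MTJ vertex angles from landmark triples,
  per-embryo fiber-detachment incidence (% of muscle segments with
  detached fibers, mean ± SEM per group), MTJ failure fractions, and
  mosaic transplanted-cell attachment rates.
* **Escape-response motility**: time to exit a 10 mm arena after a touch
  stimulus, with sub-millisecond interpolation, best-of-repeated-pokes
  selection, and the pooled slowest-exiter imputation rule for
  non-responders.
* **Statistics**: SEM, two-tailed paired Student t tests (Welch fallback
  for unequal groups), significance stars, and supplement-dosing
  arithmetic.
* **Synthetic data**: seedable generators for chevron-band micrographs
  with controllable disorganization (BM holes, speckle, blur, noise),
  binomial detachment cohorts, and escape trajectories — so the whole
  pipeline is testable without any imaging data.

See `docs/methods.md` for the model, parameter meanings, and limitations.

## Worked example

```python
import mtjquant as m

# two cohorts of synthetic micrographs: organized vs holey basement membrane
def cohort(hole_fraction, seeds):
    out = []
    for s in seeds:
        params = m.SceneParams(image_size=(256, 256), hole_fraction=hole_fraction,
                               speckle_density=3.0, noise_sd=20.0, seed=s)
        image, truth = m.generate_chevron_micrograph(params)
        out.append(m.multiscale_anisotropy(image))   # 1.88–4.02 µm grid
    return out

table = m.compare_anisotropy(cohort(0.0, range(8)), cohort(0.6, range(8, 16)))
print(table[["scale_um", "mean_a", "mean_b", "p_value", "flag"]].round(4))
```

```
   scale_um  mean_a  mean_b  p_value     flag
0    1.8800  0.1380  0.0632   0.0005  p<0.001
1    2.1339  0.1614  0.0687   0.0002  p<0.001
2    2.4220  0.1810  0.0736   0.0001  p<0.001
3    2.7491  0.2100  0.1036   0.0003  p<0.001
4    3.1204  0.2314  0.1153   0.0006  p<0.001
5    3.5417  0.2521  0.1516   0.0070   p<0.01
6    4.0200  0.2712  0.1910   0.0162   p<0.05
```

The intact-BM cohort (`mean_a`) is more anisotropic than the holey cohort
(`mean_b`) at every scale, and the paired t test flags the difference —
the organized-vs-disorganized contrast the anisotropy factor exists to
detect. Counting metrics work on plain tables:

```python
rate = m.mosaic_detachment_rate(m.MosaicCellCounts("unstressed", 523, 10))
print(rate.percent_rounded)        # 1.9  (% of transplanted cells detached)
print(round(m.supplement_molarity(5.0, 123.11, 6.0), 2))   # 6.77 (µM niacin)
```

## Command line

```sh
mtjquant simulate --n-images 4 --hole-fraction 0.6 --noise-sd 20 --seed 1 --out scenes/
mtjquant wtmm --scales 1.88,2.75,4.02 --out results/ scenes/scene_000.tif
mtjquant angles traces.csv --out results/
mtjquant detachment cohort.csv --out results/
mtjquant motility trials.csv --out results/
mtjquant report --group-a results_a/anisotropy.csv --group-b results_b/anisotropy.csv --out cmp/
```

Micrographs are 8/16-bit grayscale TIFFs with the pixel size (µm) in a
sidecar YAML or `--pixel-size-um`; tables are headered CSV; outputs are CSV
plus optional PNG overlays (maxima nodes red, chains blue, gradient
vectors green) and a run log that makes every output regenerable from
config + seed.

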