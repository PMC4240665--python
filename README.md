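# percmorph

Geomatic morphometrics of percussive-damage patterns on 3D-scanned stone
surfaces.

Archaeologists and primatologists studying percussive technology
(hammerstones, anvils, nut-cracking stones) need to tell anthropogenic
use-wear apart from natural abrasion on river cobbles — historically a
qualitative judgement. `percmorph` implements a quantitative pipeline that
treats the scanned stone surface as a micro-landscape and borrows the
standard toolkit of terrain analysis:

1. **TIN → DEM** — the triangulated scan mesh is projected onto a regular
   grid by linear (barycentric) interpolation, giving a micro-DEM of the
   surface (millimetre units throughout).
2. **TPI** — the topographic position index
   `TPI_i = z_i − mean(z_j : j in window(i))` maps micro-rugosity: positive
   at local peaks, negative in local valleys.
3. **Getis-Ord Gi\*** — the self-inclusive local spatial-autocorrelation
   statistic

   `Gi*(i) = (Σ_j w_ij x_j − X̄ W_i) / (S √[(n U_i − W_i²)/(n − 1)])`

   flags cells embedded in significant clusters of high ("hot", peaks) or
   low ("cold", valleys) TPI, with binary symmetric weights `w_ij`
   (8-neighbour + self by default), `W_i = Σ_j w_ij`, `U_i = Σ_j w_ij²`,
   and `X̄`, `S` the mean and population s.d. over the `n` valid cells.
   Cells with two-tailed `p < 0.001` (|z| ≥ 3.29) are classed hot/cold.
4. **Damage polygons** — connected significant clusters are traced along
   cell edges and measured: planar area, staircase perimeter, maximum
   length/width, and displaced volume against a least-squares reference
   plane fitted to the surrounding undamaged cells. The headline shape
   metric is the allometry-corrected **perimeter²/volume ratio** (jagged,
   shallow percussive damage scores high; smooth, deep natural pits score
   low), complemented by the per-specimen **hot/cold area ratio**.
5. **Group statistics** — two-sided Mann-Whitney U tests with Bonferroni
   correction compare groups (e.g. experimental vs natural vs
   archaeological) on both metrics.

Because reference 3D scans of damaged stones are rarely shareable, the
package ships a **synthetic cobble-surface simulator** that generates the
two damage morphologies (smooth rounded natural cupules and bosses vs
crushed jagged percussion patches) with ground-truth masks, so the whole
chain is testable end to end.

## Worked example

```bash
python examples/01_detect_damage_on_one_surface.py
```

```
cells analysed:         20736
significant hot cells:  449
significant cold cells: 291
hot polygons:           31
cold polygons:          29
hot/cold area ratio:    1.571
median hot perimeter^2/volume: 805 mm^-1
fraction of truly damaged cells flagged: 0.21
```

A simulated hammerstone surface of 150×150 cells (0.1 mm pitch) yields 60
significant damage polygons. The hot/cold area ratio above 1 and the high
perimeter²/volume of the hot polygons are the twin signatures of crushed
percussive texture; a naturally abraded surface produces a ratio well
below 1 and a median ratio around 200 mm⁻¹ (run
`examples/03_group_discrimination_study.py` for the group-level contrast,
where both metrics separate the classes at Bonferroni-corrected
p < 0.001 with the anthropogenic group higher).

The same analysis is available from the shell:

```bash
percmorph simulate --out-dir bench --n-per-class 12 --seed 42
percmorph study bench/manifest.csv --out-dir results
percmorph specimen scan.ply --out-dir out --cell-size 0.1  # a real scan
```

## Library layout

| module | contents |
|---|---|
| `percmorph.mesh_io` | PLY/OBJ/STL reading, mesh validation, vertex spacing, manifests |
| `percmorph.rasterize` | TIN→DEM linear interpolation, ESRI ASCII grid I/O |
| `percmorph.tpi` | moving-window TPI (square/annulus) with edge masking |
| `percmorph.hotspot` | spatial weights, Gi* z-scores, hot/cold classification |
| `percmorph.polygons` | cluster tracing, area/perimeter/volume, p²/V, specimen summaries |
| `percmorph.stats` | Mann-Whitney U (exact/approximate), Bonferroni, group comparisons |
| `percmorph.synthetic` | parameterised surface simulator + labelled benchmarks |
| `percmorph.pipeline` / `percmorph.cli` | per-specimen and study orchestration, `percmorph` command |

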