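# fibremetrics

Quantification of fibrillar pattern in images of extracellular matrix (ECM)
and other filamentous networks.

Tissue architecture is shaped by the fibrous ECM — collagen, fibronectin and
friends — and its organisation changes with ageing, wound healing, fibrosis
and cancer: isotropic, curly matrices straighten and align around aggressive
tumours. `fibremetrics` turns a raw 2-D matrix image (histochemical stain,
immunofluorescence, second-harmonic generation, or synthetic) into a single
row of pattern metrics, so that different tissues, treatments or patients
can be compared quantitatively. It is aimed at cell and tissue biologists
and pathologists who need a reproducible, scriptable measure of matrix
pattern rather than a visual impression.

## What it computes

The pipeline first extracts the fibre network: fibres are curvilinear
ridges, detected by Hessian (second-derivative) analysis of the
Gaussian-smoothed image at a scale matched to the chosen line width, with
subpixel centreline localisation, hysteresis linking, and pruning of
branches shorter than a minimum size. Detection can sweep several line
widths (increments of 5) and amalgamate the masks when thin and thick
fibres coexist.

From the fibre network and the mask it reports, per image:

| metric | definition |
|---|---|
| end points *E* | fibre termini not at a junction |
| branch points *B* | distinct junction loci (a 4-way crossing counts once) |
| total length *L* | Σ polyline lengths (µm if calibrated, else px) |
| HGU | hyphal growth unit, *L/E* — length per end point |
| average fibre length | *L* / (0.5 (*E* + *B*)) |
| fibre thickness | matrix area (HDM) / *L* |
| curvature | mean absolute turning angle stepping each fibre at the chosen window(s) |
| HDM | high-density matrix: fraction of pixels ≥ threshold after contrast saturation |
| alignment | coherency *a* = (λ_max − λ_min)/(λ_max + λ_min) of the gradient structure tensor *J* = [⟨f_x,f_x⟩_w ⟨f_x,f_y⟩_w; ⟨f_x,f_y⟩_w ⟨f_y,f_y⟩_w]; 0 = isotropic, 1 = perfectly aligned |
| fractal dimension | box-counting slope of log N(ε) vs log(1/ε), ∈ [1, 2] |
| lacunarity | gliding-box Λ = \|s²/μ² − 1\| of per-box mass, averaged over box sizes |
| gap sizes | maximal inscribed circles fitted iteratively into matrix-free space |

Raw *E*, *B*, *L* scale with image resolution, so the normalised versions
(*E/L*, *B/L*, *L*/area) are also reported and are the ones to compare
across studies.

No external data are needed anywhere: the `synthetic` module generates
fibre scenes with known ground truth (centrelines, counts, orientations),
analytic oracle patterns (gratings, rings, Sierpinski carpets, grids), and
the acquisition degradations (blur, noise, downsampling, under-exposure)
used to probe robustness.

## Worked example

Render two synthetic cell-derived-matrix-like scenes — one aligned (5°
orientation jitter), one isotropic — and run the batch pipeline:

```python
from pathlib import Path
from fibremetrics.synthetic import SceneSpec, render_scene
from fibremetrics.image import write_gray
from fibremetrics.params import ParameterSet
from fibremetrics.batch import run_batch

inp = Path("images"); inp.mkdir(exist_ok=True)
for name, mode, seed in [("aligned", "aligned", 1), ("isotropic", "isotropic", 2)]:
    img, _ = render_scene(SceneSpec(image_size_px=256, n_fibres=25,
                                    orientation_mode=mode, jitter_deg=5,
                                    seed=seed, fibre_width_px=4))
    write_gray(inp / f"{name}.png", img)

params = ParameterSet(line_width_min_px=4, line_width_max_px=4, gap_analysis=True)
result = run_batch(inp, params, "out")
```

`out/summary.csv` then holds one row per image (excerpt):

```
     image_id  endpoints  branchpoints  total_length  alignment      hdm  fractal_dim  lacunarity  norm_endpoints  curvature_w40  gap_count  mean_gap_area
  aligned.png         12            32       2458.74   0.944324 0.184692      1.26136     1.46728        0.004881        5.11205        119        394.705
isotropic.png         17           110       2931.93   0.278169 0.176758      1.27455     1.29423        0.005798            NaN        115        412.641
```

Reading it: the aligned field scores coherency 0.94 (near-perfect common
orientation) against 0.28 for the isotropic one — the single most
discriminating column. The isotropic scene's criss-crossing fibres produce
more branch points (110 vs 32) and a curvature value that is missing (NaN)
because junctions cut its fibres into segments shorter than two 40 px
curvature windows; with a dense network, choose a smaller window. HDM and
fractal dimension are similar — both scenes carry about the same amount of
matrix — which is exactly why a panel of metrics, not any single one, is
needed. Alongside the CSV the run writes each fibre mask, the
HDM-thresholded image, a per-image gap CSV, the archived parameter file and
a log.

The same pipeline is available from the shell:

```sh
fibremetrics params > params.txt            # commented template
fibremetrics run --input images --params params.txt --output out --gap-analysis
fibremetrics fixtures --out demo            # synthetic validation set
```

## Documentation

`docs/methods.md` describes the model, parameters, numerical choices and
known limitations.
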