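# dectbench

A self-contained simulation testbench for **projection-domain dual-energy CT
material decomposition with object-specific scatter correction**, compared
against image-domain decomposition and conventional calibration-based
decomposition, on digital quality-assurance phantoms.

## The problem

Dual-energy CT (DECT) acquires each ray with two x-ray spectra (here 80 kV
and 120 kV), which allows expressing attenuation as a combination of two
basis materials (water and calcium) and synthesizing *virtual
mono-energetic images* (VMIs) — images of μ(E) at any chosen energy,
reported in Hounsfield units. Getting the HU values *quantitatively right*
is hard: polychromatic beam hardening and detected scatter both bias the
measurements, and the widely used image-domain decomposition inherits the
beam-hardening errors of the underlying single-energy reconstructions.

The method at the core of this package works in the projection data domain.
For the raw (uncorrected) line integrals of the low- and high-energy scans

    g_m,i = −log( ∫ W_m,i(E) · exp(−∫ μ(E, x) dt) dE + s_m,i ),

it (1) estimates and subtracts an *object-specific* scatter term s using a
two-parameter convolution model fitted per scan by a Nelder–Mead simplex
search against vendor-style water-calibrated reference data, then
(2) converts each scatter-free pair (g_HE, g_LE) into basis-material line
integrals (L_w, L_c) with two quintic bivariate polynomials fitted from the
known analytical energy response W over a dense grid of material lengths
(negative lengths included), and (3) reconstructs the length sinograms with
classical parallel-rebinned filtered backprojection into relative-density
images from which a VMI at any energy is a pixelwise linear combination.

The testbench also implements the two comparators: image-domain
decomposition (effective energies from a two-configuration calibration
phantom, 2×2 matrix inversion per pixel) and conventional data-domain
decomposition (cubic and constrained-quartic polynomials fitted from
calibration scans of the same phantom), plus digital phantoms, a
polychromatic fan-beam projector with scatter and Poisson noise, and the
full evaluation protocol (insert ROIs, beam-hardening ring error, accuracy
and noise curves over 30–140 keV).

Everything is synthetic and analytic — no scanner data are required — so
every accuracy claim can be checked against exact ground truth. See
`docs/methods.md` for models, defaults, and limitations.

## Worked example

Simulate noise-free dual-energy scans of the ACR-style phantom with scatter,
run the projection-domain pipeline, and check the 70 keV VMI:

```python
import dectbench as db
from dectbench.experiments import Bench, BenchConfig
from dectbench import decomp_image, evaluation

bench = Bench(BenchConfig(model_mismatch=False))   # matched-model scatter
phantom = db.make_acr_module_a(bench.materials)
raw_le, raw_he = bench.simulate_pair(phantom)

f_w, f_c, report = bench.data_based_densities(raw_le, raw_he,
                                              scatter_mode="known")
vmi = decomp_image.synthesize_vmi(f_w, f_c, 70.0, bench.water, bench.calcium)
for name, (roi, mat) in bench.acr_rois().items():
    mean_hu = evaluation.roi_stats(vmi, roi)[0]
    gt = evaluation.gt_hu(mat, 70.0, bench.water)
    print(f"{name:14s} {mean_hu:8.1f} HU   (ground truth {gt:8.1f})")
```

prints

```
bone             998.5 HU   (ground truth    999.3)
polyethylene     -90.9 HU   (ground truth    -89.8)
acrylic          124.2 HU   (ground truth    125.6)
air             -998.2 HU   (ground truth   -998.9)
water             -0.1 HU   (ground truth      0.0)
```

i.e. with the scatter model matched exactly, the full chain — subtraction,
quintic decomposition, rebinned FBP, VMI synthesis — reproduces every insert
to within ~2 HU at 70 keV. The headline experiments instead use a
*model-mismatch* scatter truth (wider kernel plus a constant floor than the
estimator assumes), under which water stays below 1% relative error across
30–140 keV while the solid inserts degrade gracefully.

The same pipelines are scriptable from the shell:

```bash
dectbench experiment accuracy --seed 1 --out-dir runs/accuracy
dectbench experiment scatter-ablation --seed 1 --out-dir runs/ablation
dectbench experiment conventional --seed 1 --out-dir runs/conventional
```

Each run directory receives metric CSVs, a JSON report with the estimated
scatter parameters (α, β, iteration counts) and effective energies, TIFF/npy
image panels, a provenance-stamped config, and a log.

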