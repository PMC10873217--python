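# petnoise

Automated global noise measurement for PET SUV volumes.

The central quantity is the **Global Noise Index (GNI)**: each transversal
slice of a tissue-masked SUV volume is tiled into non-overlapping 8×8 blocks,
each block is reduced to the sample standard deviation of its in-mask voxels
("macro pixel"), all macro-pixel values of the whole imaging volume are
pooled into a uniform-bin histogram, and the mode bin center is the GNI — a
single surrogate for the global image noise level. The package also provides
the manual reference measurement (cubic VOI mean/SD), a statistical
validation battery (z-scoring, paired permutation Kolmogorov–Smirnov test,
Spearman correlation with Chan's verbal scale, ROC/AUC with DeLong CI and
Youden-optimal cutoff), and a synthetic whole-body phantom generator with
known ground-truth noise so the whole pipeline is testable without patient
data.

## Library quick start

```python
import petnoise as pn

vol = pn.read_volume("study.nii")              # or a DICOM series directory
result = pn.global_noise_index(vol)            # default params: threshold 0.15,
print(result.gni, result.n_macro_pixels)      # block 8, bin width 0.01

series = pn.slicewise_gni(vol)                 # per-slice GNI (NaN = no tissue)
voi = pn.cubic_voi_noise(vol, (120.0, 130.0, 400.0), edge_mm=20)

# synthetic phantom with known noise
spec = pn.PhantomSpec(sigma_ref=0.15)
vol, truth = pn.make_phantom(spec, bed_time_s=60, recon_label="Q.Clear 450")
```

## Command line

```bash
petnoise gni study1.nii study2.nii --out results/            # GNI per study
petnoise slicewise study1.nii --out slices.csv               # per-slice series
petnoise voi study1.nii --table vois.csv --out voi_out.csv   # cubic VOIs
petnoise phantom --out cohort/ --subjects 5 --seed 1         # synthetic cohort
petnoise validate --table cohort/noise_table.csv --out val/  # statistics
```

Key flags: `--threshold` (SUV value or `otsu`), `--block-size`,
`--bin-width`, `--min-valid-fraction`, `--permutations`, `--seed`. Every
output JSON embeds the effective parameter set, so identical configs produce
byte-identical numeric outputs.

`petnoise phantom` writes a cohort of synthetic volumes (noise SD scaling as
the inverse square root of bed time; a small Gaussian smoothing standing in
for the stronger regularization level), plus a noise table with GNI and
liver/lung VOI SDs per condition. `petnoise validate` consumes such a table
(or one built from real measurements) and reports paired KS tests on
z-scored values, Spearman correlations with Chan labels, and — when quality
labels are present — ROC analysis per reconstruction label.

## Tests and acceptance report

```bash
python -m pytest -q                                   # full suite (~1 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalence of macro-pixel SDs, σ-recovery on Gaussian phantoms,
bed-time √t law, smoothing monotonicity, shift/scale invariances, statistics
calibration, end-to-end pipeline, determinism). `scripts/acceptance.py`
exercises the pipeline end to end and writes the (empty — the validation is
property-based, no numeric targets are defined) acceptance-target JSON.
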