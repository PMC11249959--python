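# dtialps

Quantification of glymphatic-system function from diffusion MRI via the
DTI-ALPS index ("analysis along the perivascular space"), with the
cross-sectional and longitudinal statistics used to study it in genetic
frontotemporal dementia cohorts — exercised end-to-end on synthetic
diffusion phantoms and simulated cohorts.

The package is aimed at neuroimaging researchers who want (i) a tested,
reproducible implementation of the ALPS computation from tensor volumes,
(ii) generators for ground-truth phantoms and GENFI-like cohorts to
validate analysis pipelines, and (iii) the associated statistical
battery: covariate-adjusted group comparisons with FDR-corrected
pre-defined contrasts, association models, Z-score stratification and a
mixed-effects disease-progression model.

## The index

At the level of the lateral ventricle body, medullary veins run
left–right (x), projection fibres head–foot (z) and association fibres
anterior–posterior (y).  Perivascular fluid movement along the veins
adds diffusivity along x in both fibre regions, while the directions
perpendicular to both the fibres and the veins are unaffected.  With
5 mm spherical ROIs in the projection and association regions of each
hemisphere,

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

per hemisphere, and the bilateral index is the average of the left and
right indices.  An index near 1.0 means no preferential perivascular
diffusion (impairment floor); healthy white matter sits around 1.3.
Tensors are fit per voxel by a two-stage weighted log-linear fit
(ln S = ln S0 − b gᵀDg), and ROI placement is quality-checked by mean
FA, principal-eigenvector alignment with the expected fibre axis, and
voxel count.

## Worked example

The numbered scripts under `analysis/` run the full study sequence on
synthetic data (all outputs under `results/analysis`):

```
python analysis/01_simulate.py --seed 1      # phantoms + cohort + visits
python analysis/02_compute_alps.py --seed 1  # ALPS on the phantoms
python analysis/03_cross_sectional.py --seed 1
python analysis/04_longitudinal.py --seed 1
```

Stage 2 verifies the computed index against the phantom's closed-form
ground truth (λ⊥ + ε)/λ⊥ = (0.40 + 0.12)/0.40 = 1.30:

```
    subject  alps_left  alps_right  alps_mean  qc_pass
phantom_000        1.3         1.3        1.3     True
...
max |computed - ground truth| over 10 phantoms: 0.00e+00
```

Stage 3 prints the covariate-adjusted (age, sex, site) estimated
marginal means of ALPS and the pre-defined contrasts for a simulated
374-subject cohort (seed 1):

```
  NC_old           1.327 +/- 0.034  (n=33)
  NC_young         1.290 +/- 0.027  (n=50)
  presymptomatic   1.310 +/- 0.014  (n=199)
  symptomatic      1.236 +/- 0.024  (n=92)
  NC_old vs symptomatic: diff +0.091, p_fdr=0.0264 *
  presymptomatic vs symptomatic: diff +0.074, p_fdr=0.0264 *
  cdr_ftld        beta=-1.115 (se 0.157), p=0.0000, n=291
```

i.e. the symptomatic group shows the lowered index and the generated
severity-on-ALPS slope (−1.16) is recovered.  Stage 4 stratifies
carriers by baseline ALPS Z-score against the pooled non-carrier
reference and fits the mixed progression model:

```
  low      beta=+0.182 [+0.158, +0.206], p=0.0000
  average  beta=+0.049 [+0.033, +0.064], p=0.0000
  high     beta=-0.024 [-0.051, +0.003], p=0.0838
```

Low baseline ALPS progresses fastest; high baseline ALPS stays flat —
matching the generating slopes (0.20 / 0.05 / −0.01 CDR-FTLD units per
year).

The same stages are available as a CLI (`dtialps simulate | alps |
stats | run-all`) driven by a YAML configuration with a strict schema;
every run writes a manifest with the config hash, per-stage seeds and
output file hashes, and re-running with the same seed reproduces all
outputs byte-identically.

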