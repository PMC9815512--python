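# imdkit

Analysis toolkit for **in situ metabolic perturbation screens with
implantable microdevices** (IMDs).  An IMD carries ~18 drug-loaded
reservoirs that release microdoses of metabolites or inhibitors into the
surrounding tumor tissue; multiplex immunofluorescence, MALDI mass
spectrometry imaging and GeoMx-style spatial transcriptomics then read out
the local response.  `imdkit` implements the downstream quantification for
all three readouts, together with a synthetic-data generator that plants
known effect sizes so the whole pipeline is testable end to end without
tissue data.

It is aimed at computational biologists working with microdevice
perturbation data (or any reservoir-centred point-pattern readout) who need
reproducible, scriptable versions of the image-analysis arithmetic that
usually lives in vendor software.

## What it computes

**1. Marker response around reservoirs** (`PerturbationModel`).  The region
around each reservoir is expanded to 1,200 µm and divided into four
concentric sub-ROIs of 300 µm depth.  For tumor *t* and condition *c* the
effect is the log2 fold change of marker-positive cell density against the
same device's empty (control) reservoirs:

    log2FC(t, c, m) = log2( d_roi(t, c, m) / d_ctrl(t, m) ),
    d = (count + pseudocount) / area[mm²]

Per-tumor fold changes are aggregated as mean ± SEM and tested with a
two-tailed unpaired Student's *t* test against the device's
control-vs-control fold changes (a null sample centred at zero); percent
change is `(2^log2FC − 1)·100`.  Per-ring densities are kept and screened
for artefact rings (flagged, never silently dropped).

**2. Marker-guided paired-ROI spatial metabolomics**
(`PairedMetabolomicsModel`).  A kernel density map of marker-positive cells
(CD3/CD8/FOXP3) is thresholded at a quantile; connected components become
fixed-area disc hotspots, and each hotspot is coupled with the nearest
disjoint equal-area disc whose marker count is lower by at least 0.5 log2
units.  Raw ion counts per metabolite are extracted from the co-registered
MALDI raster for both discs, per-pair log2 fold changes are tested with a
paired *t* test (BH-adjusted across metabolites), and significant lists
feed a hypergeometric over-representation test on user-supplied pathway
sets, Pearson "metabolic signature" correlation matrices, and an
opposite-trend screen between two marker populations.

**3. CD8-infiltration classification of ST ROIs**
(`STClassificationModel`).  Each ROI's positive index = CD8⁺ cells /
nuclei; ROIs are CD8-high (> 20 %), CD8-low (< 5 %) or intermediate.
Expression is normalised per ROI to the geometric mean of a target gene
group, classes are compared per gene with *t* tests + BH, and the DE list
is fed to the shared over-representation test.

## Worked example

```python
from imdkit import simulate as sim
from imdkit import PerturbationModel

# arginine-release preset: plants a +75 % CD8 density change at the reservoirs
sc = sim.perturbation_scenario("ARG_CD8", seed=0, n_tumors=6)
tumors, bounds = sim.gen_experiment(sc)
res = PerturbationModel.from_tumors(tumors, tissue_bounds=bounds).fit()
print(res.summary())
```

```
Marker response vs internal control (log2 fold change of density)
=================================================================
condition marker  mean_log2fc     sem  n_tumors  p_value  percent_change stars
  ARG_CD8    CD3       0.3839  0.0323         6   0.0000         30.4833    **
  ARG_CD8    CD8       0.7764  0.0300         6   0.0000         71.2838    **
  ARG_CD8  FOXP3       0.0375  0.0388         6   0.9445          2.6348      
(* p<0.05, ** p<0.005)
```

The CD8 row recovers the planted +75 % (here +71 % for one seed; the
replicated-seed mean lands within a couple of points).  CD3 rises too
because CD8⁺ cells are CD3⁺; FOXP3 is untouched, as planted.  The
metabolomics stage reads the same way:

```python
from imdkit import PairedMetabolomicsModel
img, cells = sim.gen_ion_image(sim.metabolomics_scenario("CD8_HOTSPOT", seed=3))
print(PairedMetabolomicsModel(img, cells, "CD8").fit().summary())
```

```
Paired metabolomics — marker CD8
hotspots: 6   matched pairs: 6
significant metabolites (raw p < 0.05): 2
       metabolite  mean_log2fc  p_value  p_adjusted
N-acetyl-cysteine       0.9653   0.0000      0.0000
      glutathione       0.8451   0.0001      0.0004
```

Exactly the two planted antioxidants are flagged, both positive.

A CLI mirrors the stages (`imdkit simulate | perturb | metpair | stclass |
report`); `imdkit report --config run.yaml` executes a configured pipeline
and writes a manifest that reproduces the run byte for byte.

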