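# pedci

Composition analysis of pigment epithelial detachments (PEDs) on OCT B-scans.

## The problem

In neovascular age-related macular degeneration (nAMD), the retinal pigment
epithelium lifts off Bruch's membrane, forming a PED that may contain serous
fluid, neovascular tissue, fibrous scar, or any mixture of the three. The mix
matters clinically — fibrosis signals treatment response, neovascular tissue
signals active leakage — but the three materials overlap heavily in raw OCT
intensity, so clinicians usually collapse them into the umbrella term
"fibrovascular PED". Their OCT *textures* differ, though: serous fluid is dark
and uniform, fibrous scar is bright and uniform, and neovascular tissue is
mid-bright but riddled with hyporeflective vascular pockets, i.e. locally
heterogeneous.

`pedci` turns that observation into a per-pixel **scarring likelihood** via a
kernel-filter cascade and summarizes each PED with three **composition
indices**. It is aimed at retina researchers who have exported B-scans
(PNG/TIFF) and manual PED outlines (ImageJ ROI, CSV, or JSON) and want
reproducible composition numbers per scan and per cohort.

## The method

With `I0` the pre-processed scan (per-image min–max normalization to [0, 1],
optionally per-A-scan shadow compensation) and `AVG(·, k)` / `STD(·, k)` the
k×k moving mean / sample standard deviation (mirror-reflected borders),
computed over the PED's padded bounding box:

    I1 = AVG(I0, 7)      I2 = STD(I0, 7)      I3 = I2 / (I1 + eps)
    I4 = I0 - I3         I5 = AVG(I4, 11)     I6 = AVG(I0, 9)

    I7 = 0                where I6 <  G_T1        (dark neighborhood)
       = clip(I5, 0, 1)   where I6 >= G_T1

`I3` is the local coefficient of variation, so `I5` rewards pixels that are
bright *and* homogeneous. Each PED pixel is then classified

    serous        I7 = 0
    neovascular   0 < I7 < G_T2
    fibrous       I7 >= G_T2

and the indices are area fractions of the whole PED:

    PEDCI-S = serous area / total PED area
    PEDCI-N = neovascular area / total PED area
    PEDCI-F = fibrous area / total PED area

Defaults: `G_T1 = 0.25`, `G_T2 = 0.6`, pixel scales 4 µm (axial) × 7 µm
(transverse). Absolute areas are reported in mm². PEDs smaller than 100 µm in
bounding-box height or width are flagged as excluded.

The package also ships two comparison segmenters (3-level Otsu thresholding
and K-means on intensity + local texture), observer-agreement statistics
(ICC(2,1) for repeatability/reproducibility, Bland–Altman limits at
mean ± 2 SD), and a synthetic phantom generator that produces OCT-like scans
with known composition for validation.

## Worked example

```bash
python examples/01_phantom_pipeline.py
```

generates the default three-compartment phantom (30% serous / 50%
neovascular / 20% fibrous by construction), runs the cascade, and compares
the recovered indices with the generator's ground truth:

```
PED size: 22305 pixels
overall pixel accuracy: 0.908
  serous       PEDCI est=0.359 truth=0.303 |err|=0.056
  neovascular  PEDCI est=0.479 truth=0.498 |err|=0.019
  fibrous      PEDCI est=0.162 truth=0.199 |err|=0.037
```

91% of PED pixels get the correct tissue label and each index is recovered
within 0.06; the residual error is concentrated at compartment boundaries,
where any window-based filter mixes tissues. The other scripts under
`examples/` cover file-based analysis, the Otsu/K-means comparison, agreement
statistics, and shadow compensation.

The same pipeline is available from the shell:

```bash
pedci analyze --image scan.png --roi ped.roi --out results/
pedci batch --manifest cohort.csv --out results/
pedci phantom --out phantom_out/ --seed 0
pedci agreement --scores grades.csv --out icc.csv
```

## Layout

| path | contents |
| --- | --- |
| `src/pedci/io.py` | B-scan/polygon reading, ImageJ ROI codec, rasterization |
| `src/pedci/preprocess.py` | normalization, shadow compensation |
| `src/pedci/filters.py` | the I0→I7 kernel cascade |
| `src/pedci/classify.py` | classification, PEDCI, size gate, overlays, cohort summary |
| `src/pedci/baselines.py` | multi-Otsu and K-means comparators |
| `src/pedci/agreement.py` | ICC(2,1), Bland–Altman |
| `src/pedci/phantom.py` | synthetic phantom generator + recovery evaluation |
| `src/pedci/cli.py` | `pedci` command-line tool |
| `docs/methods.md` | models, assumptions, parameter rationale, limitations |
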