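# nanotube-quant

Automated quantification of **tunneling-nanotube (TNT)-like membrane
protrusions** and **intercellular organelle transfer** in two-channel
fluorescence micrographs.

Macrophages extend long, thin, actin-rich membrane channels (TNTs) that can
deliver organelles — e.g. cystinosin-bearing lysosomes or frataxin-tagged
mitochondria — into the cytosol of distant cells. Screening this behaviour at
scale means answering two questions for every stitched wide-field image:

1. **Which labeled cells bear TNT-like protrusions?** (protrusion pipeline)
2. **Which recipient cells contain donor-tagged puncta?** (transfer pipeline)

`nanotube-quant` implements both as reproducible, configurable pipelines over
calibrated rasters, together with a synthetic scene generator that provides
exact ground truth for every stage, so the whole stack is testable without any
microscope data.

## Method

**Protrusion detection.** The cell channel is thresholded (Otsu by default),
objects ≥ 100 µm² are kept as cells (holes filled), and each cell mask *M* is
morphologically opened,

&nbsp;&nbsp;&nbsp;&nbsp;γ(M) = δ<sub>B</sub>ⁿ(ε<sub>B</sub>ⁿ(M)),

with a small square structuring element *B* (default 3×3, *n* = 7 passes).
Opening erases peripheral structures thinner than ≈ 2·*n* px while the
dilation restores the central body; the **residue** *M* \ γ(M) contains the
candidate protrusions. Residue components pass the TNT shape screen when
(all bounds inclusive):

| descriptor | definition | bound |
|---|---|---|
| area | *n*<sub>px</sub>·s² | ≥ 20 µm² |
| longest axis | maximum Feret diameter | ≥ 10 µm |
| circularity | area / (π/4 · Feret²) | ≤ 0.6 |
| box-area ratio | bbox area / object area | ≥ 1.9 |

A cell is **protrusion-positive** iff a surviving protrusion overlaps or
borders its opened body; fields are summarized as percent-positive cells.

**Transfer quantification.** Recipient cells (≥ 100 µm²) are segmented from
the DsRed channel and applied as ROIs to the donor channel, whose background
threshold comes from donor-free control images (99.9th percentile by
default). Donor components touching the ROI's 1-px inner boundary band are
excluded (overlap artifacts), components larger than 25 µm² are excluded
(an organelle punctum is small), and a recipient is **donor-positive** iff at
least one punctum survives. Both exclusion counts are reported per recipient.

**Morphometry.** All descriptors (area, Feret length, circularity,
equivalent-ellipse aspect ratio, box-area ratio) are exposed for any region,
with manual cut-line separation of protrusions from cell bodies for precise
measurement of individual protrusions.

## Worked example

Generate a synthetic co-culture field and run both pipelines:

```bash
cat > spec.yaml <<EOF
seed: 3
field_size: [768, 768]
n_macrophages: 10
n_fibroblasts: 5
EOF
nanotube-quant simulate --spec spec.yaml --out scene
nanotube-quant protrusions --cell-channel scene/cell.tif --pixel-size 0.5 --out prot
```

prints the per-field summary (3 of the 10 generated macrophages carry a
qualifying TNT-like ribbon, and all three are recovered):

```
group  n_cells  n_positive  n_degenerate  percent
field       10           3             0     30.0
```

With a donor-free control for background calibration, the transfer pipeline

```bash
nanotube-quant transfer --donor scene/donor.tif --recipient scene/recipient.tif \
    --controls ctrl.tif --pixel-size 0.5 --out tr
```

prints

```
{"n": 5, "n_positive": 3, "percent": 60.0}
```

i.e. 3 of the 5 fibroblasts contain at least one accepted donor punctum —
exactly the generated ground truth (`scene/ground_truth.json`). Each run also
writes per-cell/per-recipient CSV tables and a QC overlay PNG (green =
positive, red = negative).

The same operations are available as a library:

```python
from nanotubequant import SceneSpec, generate_scene, analyze_cell_channel, percent_positive

scene = generate_scene(SceneSpec(seed=3, field_size=(768, 768), n_macrophages=10))
results = analyze_cell_channel(scene.cell)
print(percent_positive(results))
```

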