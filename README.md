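# mythscreen

Quantification pipeline for **arrayed membrane yeast two-hybrid (MYTH)
screens**, plus the matching nuclear-envelope GFP quantification recipe for
confocal z-stacks.

In a split-ubiquitin MYTH screen, a membrane bait protein is tested against
an arrayed prey library: bait–prey diploids are selected in 96-spot format
(colony *area* = mating success) and pinned in technical quadruplicate onto
selective 384-spot test plates, where reporter activation lets colonies grow
(colony *density* = interaction strength). This package turns those plate
photographs into per-prey interaction calls and cross-bait comparisons, for
anyone running or reanalysing arrayed colony screens.

## What it computes

Per test spot, the **density** is the integrated above-background intensity
over the spot window (local corner-annulus background). Densities are
normalized by the min–max-scaled diploid colony area of the source well:

    d̂ᵢ = dᵢ / ãᵢ ,   ãᵢ = (aᵢ − a_min) / (a_max − a_min)

wells with ãᵢ < ε (default 0.05) are flagged `failed_mating` and reported as
`no_call` rather than negative. The positive cutoff **c** is calibrated from
manually categorized colonies as the 25th percentile (linear interpolation)
of the "weak" class densities, and a prey with spot densities d̂₁…d̂ₙ is
called **positive** iff

    #{i : d̂ᵢ > c} ≥ n/2        (strict inequality; ties count as below)

with the reported per-prey density the mean over all n replicate spots.
Downstream: replicate agreement (|A∩B|/|A∪B|, Pearson r of zero-filled
densities), per-bait ≥2-fold enrichment, Venn partitions, upper-tail
hypergeometric term enrichment against the library background with
Bonferroni correction, and complete-linkage Euclidean row clustering for
heatmaps. The `nuclei` module implements: max projection → rolling-ball
background subtraction (r = 20 px) → Gaussian blur → IsoData threshold →
particles of 4–12 µm² with circularity 4π·A/P² ≥ 0.3 → mean intensity per
nucleus on the sum projection.

A first-class synthetic-data module renders plates and z-stacks with exact
per-spot/per-nucleus ground truth, so every stage is validated by recovery
tests — no raw screen images are required. See `docs/methods.md` for the
full model and conventions.

## Worked example

Simulate a one-plate screen (96 prey in quadruplicate), quantify it and call
interactions:

```python
from mythscreen import synth, calling
from mythscreen.layout import default_layout

cfg = synth.SynthScreenConfig(n_plates=1, seed=11)
library = default_layout(1)
classes = synth.draw_interactor_classes(sorted(library.preys()), cfg)
screen = synth.simulate_screen(cfg, library, classes)
labels = synth.simulate_labeled_colonies(cfg, n=120, seed=12)

calls, spots, cutoff = calling.run_screen(
    screen.test_images, screen.diploid_images, library,
    labels=labels, bait="cut11",
)
print(f"cutoff = {cutoff:.0f}")
print(f"positive: {int(calls.positive.sum())} / {len(calls)} prey")
```

prints

```
cutoff = 14537
positive: 14 / 96 prey
```

i.e. the cutoff calibrated from the 120 labelled colonies is 14 537 density
units, and 14 of the 96 prey pass the half-of-quadruplicate rule. Checking
against the generator's truth table: the simulation planted 15 interactors;
14 are called positive and the 15th was a simulated mating failure, which
the pipeline reports as `no_call` (status-tracked, not a silent negative).

The same stages are available from the shell:

```sh
mythscreen simulate --n-plates 1 --seed 5 --outdir sim
mythscreen quantify --test-images sim/test_p1.tif \
    --diploid-images sim/diploid_p1.tif --layout sim/layout.csv --out spots.tsv
mythscreen calibrate --labels sim/labels.csv        # prints the cutoff
mythscreen call --spots spots.tsv --cutoff 16033 --out calls.tsv
mythscreen nuclei --stack stack.tif --pixel-size 0.1 --out nuclei.tsv
```

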