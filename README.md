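# coactmap

Antagonist-coactivation mapping from high-density and simulated-bipolar
surface EMG of the triceps surae.

## The problem

After a stroke, plantar-flexor muscles often activate during *dorsiflexion*
effort — antagonist coactivation that impedes movement. Clinicians and
researchers quantify it with the **coefficient of antagonist activation**:

```
CAN = RMS(EMG during antagonist effort) / RMS(EMG during the muscle's own agonist MVC)
```

With a single bipolar electrode pair this yields one number (**BipCAN**).
With a high-density grid of electrodes over gastrocnemius medialis (GM) and
linear arrays over soleus (SO), the ratio can be formed per channel, and the
normalization choice matters:

* **CsCAN** (channel-specific): each channel is divided by the agonist-MVC
  RMS of the *same* channel;
* **OvCAN** (overall): every channel is divided by the *maximum* agonist-MVC
  RMS across the detection system.

By construction `OvCAN(ch) ≤ CsCAN(ch)` on every channel, with equality
everywhere only for a spatially uniform agonist map. CAN may exceed 1 and is
never clipped. The spatial CAN map is then segmented (channels within 70% of
the map maximum, largest 4-connected component) and the CAN-weighted
centroid localizes the antagonist hotspot in normalized proximal–distal /
medial–lateral coordinates.

`coactmap` implements this whole chain — electrode-grid geometry, montage
derivation (monopolar → single-differential, simulated large-electrode
bipolar), RMS amplitude mapping with two epoching rules, the three CAN
schemes, segmentation/centroid analysis, and pooled descriptive tables —
plus a seeded synthetic HD-EMG generator with planted ground truth, so every
stage can be validated against known answers.

## Worked example

```bash
python examples/03_can_schemes.py
```

```
planted antagonist/agonist ratio: 0.45
CsCAN  mean over 59 channels: 0.450
OvCAN  mean over 59 channels: 0.443
BipCAN (single channel):          0.452
OvCAN <= CsCAN on every channel: True
```

A synthetic dorsiflexion trial is planted with an activation field 0.45× its
plantar-flexion MVC reference on the 13×5 GM grid (one missing corner → 59
valid single-differential channels). CsCAN and BipCAN recover the planted
ratio directly; OvCAN sits slightly below it because its shared denominator
is the *maximum* agonist RMS in the grid. The other `examples/` scripts show
study simulation, montage bookkeeping, hotspot localization and the full
pipeline; the library is also scriptable from the shell:

```bash
coactmap simulate --subjects 2 --alpha 0.4 --seed 5 --out study/
coactmap run --dataset study/ --out results/
coactmap report --results results/
```

## Layout

```
src/coactmap/      grids, recording I/O, montage, simulate, amplitude,
                   can, spatial, validation, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, parameters, numerical choices, limitations
```
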