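# cherenkovdsc

Synthetic skin-tone phantom study of Cherenkov surface imaging in
radiotherapy: does the light imaged during treatment still outline the
planned field when the patient's skin is dark?

During external-beam radiotherapy, secondary electrons above the Cherenkov
threshold (0.219 MeV in tissue of refractive index 1.4, since
`E_thr = m_e c² (1/√(1 − 1/n²) − 1)`) emit optical Cherenkov light that
escapes the top few millimetres of skin and maps where dose is deposited.
Epidermal melanin attenuates that light: across the melanin-index range
MI 37–120 (`MI = 100·log₁₀(1/R)` with `R` the 680 nm reflectance) the
escaping signal drops by roughly a factor of 10. This package simulates the
whole verification chain — six skin-tone phantoms, planned surface-dose maps
for three whole-breast delivery techniques (static tangents, field-in-field,
VMAT), and a pulse-gated camera with melanin-attenuated signal, ambient and
leakage background, shot and read noise — and quantifies plan-to-image
agreement with the threshold-sweep maximum Dice similarity coefficient

    DSC = 2·|A ∩ B| / (|A| + |B|)

where A is the planned dose region above a fixed 30% threshold and B the
imaged Cherenkov region above a threshold iterated from 15% to 45%, keeping
the largest DSC found. It is aimed at medical-physics researchers who want
a controlled, fully reproducible test bed for surface-imaging comparison
metrics across skin tones and delivery techniques.

## Worked example

```python
from cherenkovdsc import (
    ExperimentConfig, acquisition_seed, cherenkov_threshold_energy,
    generate_dose_map, make_phantom_presets, melanin_transmission_factor,
    run_cell, setup_seed,
)

print(round(cherenkov_threshold_energy(1.4), 3))      # 0.219 (MeV)
presets = make_phantom_presets()                       # types I..VI, MI 37..120
print(melanin_transmission_factor(120.0))              # 0.1 (factor of 10 loss)

cfg = ExperimentConfig()
dose = generate_dose_map("tangent", params=cfg.dose_params())
cell = run_cell(dose, presets[0], cfg,
                acquisition_seed(0, 0, 0, 0), setup_seed(0, 0, 0))
print(round(cell.sweep.max_dsc, 4), cell.sweep.argmax_threshold)   # 0.9862 0.32

dose_v = generate_dose_map("vmat", params=cfg.dose_params())
cell_v = run_cell(dose_v, presets[5], cfg,
                  acquisition_seed(0, 5, 2, 0), setup_seed(0, 2, 0))
print(round(cell_v.sweep.max_dsc, 4), cell_v.sweep.argmax_threshold)  # 0.4022 0.45
```

The lightest phantom under tangent fields reaches a maximum Dice of 0.986
(best image threshold 32%): the imaged light outlines the planned field
almost perfectly, limited only by the simulated re-setup error. The darkest
phantom under VMAT collapses to 0.40: with the signal attenuated tenfold and
the background accumulated over four times as many frames at twice the
leakage, no sweep threshold separates the field from the background floor —
the qualitative failure mode seen clinically for highly modulated plans on
the darkest skin.

The same experiment end to end, from a shell:

```sh
cherenkovdsc presets                       # the six phantom definitions
cherenkovdsc run-experiment --out results/run1
cherenkovdsc compare plan.tif image.tif    # your own co-registered maps
cherenkovdsc report results/run1/experiment_table.csv --plot dsc.png
```

`run-experiment` writes per-cell cumulative images (16-bit TIFF with JSON
sidecars), sweep curves, binary difference maps, the replicate table, the
per-cell summary, intensity-vs-MI and intensity-vs-CIE-L trend fits, and a
manifest logging every seed.

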