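# secmal

Secondary-malignancy risk estimation from paired proton/photon dose–volume
histograms (DVHs) of thoracic organs at risk.

Radiotherapy of mediastinal lymphoma cures young patients who then live for
decades with the dose their lungs, breasts and esophagus received. `secmal`
quantifies the resulting radiation-induced second-cancer risk for a cohort of
patients, each planned with both proton therapy and photon IMRT, and tests
whether the proton plans carry a significantly lower modelled risk. It is
aimed at medical physicists and outcome modellers doing plan-comparison
studies.

## Models

**LQ competition model (Dasu).** The probability of inducing a secondary
cancer in an organ is the volume-weighted average over the differential DVH
of a term that competes mutation induction against cell kill:

    risk = (1/Σᵢvᵢ) Σᵢ vᵢ (α₁Dᵢ + β₁Dᵢ²/n) · exp(−(α₂Dᵢ + β₂Dᵢ²/n))

where vᵢ is the volume fraction at dose Dᵢ given in n fractions,
β = α/(α/β) with α/β = 3 Gy, and α₁ comes in *total* (any cancer) and
*fatal* (lethal cancer) flavours per organ.

**Organ equivalent dose (Schneider).** OED = (1/Σᵢvᵢ) Σᵢ vᵢ·RED(Dᵢ) with
three dose–response scenarios — linear (RED = D), linear-exponential
(RED = D·e^(−α′D)) and plateau (RED = (1−e^(−α′D))/α′) — where
α′ = α₂ + (α₂/(α/β))·Dᵢ/n is the per-bin fractionation-corrected cell-kill
slope. The proton/photon **relative risk** of an organ is the ratio of its
OEDs; RR < 1 favours protons.

Cohort comparisons use two-tailed Wilcoxon signed-rank tests (exact null up
to 25 informative pairs, continuity-corrected normal approximation beyond).
Because clinical DVHs cannot ship with the package, a seeded synthetic
generator emulates the study population: 23 patients (16 female), 20–39.6
Gy(RBE) prescriptions in 10–22 fractions, photon plans with a broad low-dose
bath, proton plans with sharply reduced out-of-field dose, and occasional
lateralized cases whose proton dose to the right breast or esophagus exceeds
the photon dose.

## Worked example

```python
import numpy as np
from secmal import (DifferentialDVH, REDModel, dasu_organ_risk,
                    default_coefficients, oed)

# right lung: half the volume at 5 Gy, 30% at 15 Gy, 20% at 30 Gy, n = 18
dvh = DifferentialDVH("lung_right", np.array([5.0, 15.0, 30.0]),
                      np.array([0.5, 0.3, 0.2]))
c = default_coefficients("lung_right")  # α₁ fatal/total, α₂ from the built-in table

print(round(dasu_organ_risk(dvh, 18, c, "total").risk * 100, 2))  # 2.68
print(round(dasu_organ_risk(dvh, 18, c, "fatal").risk * 100, 2))  # 1.88
for variant in REDModel:
    print(variant.value, round(oed(dvh, variant, c, 18).oed, 2))
# linear 13.0
# linear_exponential 1.63
# plateau 4.45
```

The total induction risk of this dose distribution is 2.68% (1.88% fatal).
The linear OED is just the mean dose (13 Gy); the linear-exponential
scenario, in which cell kill wipes out most of the high-dose contribution,
is equivalent to a uniform 1.63 Gy; the plateau scenario saturates in
between (4.45 Gy).

The same pipeline runs from the shell:

```sh
secmal simulate --n 23 --female 16 --seed 42 --out cohort.csv
secmal compute --dvh cohort.csv --dialect differential --out results.csv
secmal compare --results results.csv     # Table-style RR summary + p-values
```

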