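# Methods

## Scope and data model

The package estimates radiation-induced second-cancer risk per organ at risk
(right/left lung, right/left breast, esophagus) from paired proton/photon
treatment plans. All computation runs on *differential* DVHs with
dimensionless volume fractions: both models are volume-weighted averages
over dose bins, so absolute organ volumes cancel. Cumulative planning-system
exports (volume ≥ dose) are converted on read: bin `i` gets the volume drop
between successive grid points at the interval midpoint, and the residual
volume at the last grid point stays as a terminal bin at that dose — the
standard planning-system convention, with bias bounded by half a bin width.
Zero-dose bins are retained: spared volume contributes no risk but dilutes
the volume average, which is the models' intent. Proton doses are assumed
already expressed in Gy(RBE) (constant RBE of 1.1 applied upstream); no RBE
arithmetic happens here.

## LQ competition model

Per bin, risk = (α₁D + β₁D²/n)·exp(−(α₂D + β₂D²/n)); the organ risk is the
volume-weighted mean. Both β's derive from one organ-level α/β = 3 Gy
(β = α/(α/β)); n is the planned fraction number of the whole plan, applied
to every bin — each voxel receives its bin dose spread over all n fractions.
α₁ is an ICRP-style population-averaged induction coefficient with *total*
and *fatal* variants (fatal ≤ total per organ); no age- or sex-specific
modification is applied. Built-in coefficients (per Gy):

| organ     | α₁ fatal | α₁ total | α₂    |
|-----------|----------|----------|-------|
| lung      | 0.0101   | 0.0144   | 0.129 |
| breast    | 0.0028   | 0.0144   | 0.008 |
| esophagus | 0.0014   | 0.0015   | 0.274 |

Sided organs share their pair's row. A YAML file can override any
coefficient for sensitivity analysis; the defaults stay authoritative.
Risks are stored as fractions in [0, 1] and multiplied by 100 only for
reporting.

Near D = 0 the risk is α₁D to first order; the quadratic term makes the
ratio risk/(α₁D) exceed 1 by up to a few percent at small n for low-α₂
organs, so the low-dose check asserts agreement within 5% rather than a
one-sided bound.

## Organ equivalent dose and relative risk

OED is the volume-weighted mean of RED(D) under linear, linear-exponential
and plateau dose–response scenarios, with the cell-kill slope
α′ = α₂ + (α₂/(α/β))·D/n re-evaluated **per bin** (the bin dose enters the
fractionation correction). All three scenarios coincide with the dose at
D → 0 and satisfy RED ≤ D, so OED never exceeds the maximum bin dose. A
subtlety of the per-bin correction: the plateau RED is monotone in dose at
fixed α′, but raising a bin dose also raises α′ and lowers the saturation
cap 1/α′, so the plateau OED can decrease marginally at high dose; only the
fixed-α′ shape is monotone.

Relative risk is proton OED / photon OED per organ and scenario, computed
for all three scenarios always. When the photon OED is zero the ratio is
undefined; such records are excluded from summaries and tests (not set
to 1 — there is no risk to compare, and inclusion would bias medians) and
logged.

## Paired cohort statistics

Proton-vs-photon comparisons use the two-tailed Wilcoxon signed-rank test.
Zero differences are dropped before ranking (Wilcoxon's original treatment,
the default of common clinical statistics software); absolute differences
are midranked. For ≤ 25 informative pairs — covering the 23-patient study
size — the exact null distribution of W⁺ is built by shift convolution over
the doubled midranks, which is identical to exhaustive 2ⁿ sign enumeration;
beyond that a continuity- and tie-corrected normal approximation is used.
Two-tailed p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Fewer than five
informative pairs is reported as insufficient data. No multiple-testing
correction is applied; p-values are reported raw.

Bilateral organs are summarized both per side and as per-patient left+right
sums ("combined" lung/breast): the combined median is the median of
per-patient sums, never the sum of per-side medians. Breast statistics
cover female patients only.

## Synthetic cohort generator

The generator emulates the study population, not any real plan. Each organ
DVH is a three-component mixture discretized to a fixed 0.5 Gy grid from 0
to the prescription dose: a zero-dose mass (spared volume), an exponential
low-dose tail (scatter bath; mass beyond the grid lumps into the top bin),
and a truncated-normal plateau near the prescription (in-field volume,
σ = 1 Gy, center drawn once per patient/organ at 90–98% of prescription and
shared between modalities). This is the simplest family that spans both the
photon low-dose-bath and proton distal-sparing regimes with closed-form
control of the mean dose.

Fractionation: 10–22 fractions with mode 18 (60% of draws at the mode,
otherwise triangular), dose per fraction 1.8–2.0 Gy(RBE) (70% at 2.0), and
prescription = n × d clipped to 20–39.6 Gy(RBE), keeping the three mutually
consistent. Over large cohorts the median prescription lands at 36 Gy(RBE)
and the median fraction number at 18.

Default mixtures were set from closed-form mean-dose arithmetic so that
per-organ risks and RR medians land in the direction and rough magnitude of
published proton-vs-photon mediastinal comparisons (photon lungs ≈ 2%,
proton ≈ 1% total risk per side; RR ≈ 0.3–0.5 for lungs/breasts, ≈ 0.8 for
the esophagus). The proton esophagus mixture keeps the photon tail length
and reduces mass instead of shortening the tail: the target wraps around
the esophagus, so protons spare it by volume rather than range — and a
shorter tail would concentrate dose near the linear-exponential turnover
1/α′ and invert the RR direction. These defaults are free parameters of the
emulation, not measured values.

Per-patient randomness comes from substreams seeded by (seed, patient
index), so adding a patient never perturbs earlier ones. Jitter (tail-length
scale, zero-mass shift, plateau-mass scale, plateau center) is drawn once
per organ and applied to both modalities, which makes the photon DVH
stochastically dominate the proton DVH for every non-adversarial organ; a
repair step caps the proton tail weight at the photon tail weight (excess
moved to the proton zero-dose mass) to keep the guarantee under clipping.
Dominance implies OED(linear, photon) ≥ OED(linear, proton). A configurable
fraction of patients (default 2/23) is *adversarial*: the resolved mixture
parameters of the right breast (female) or esophagus are swapped between
modalities, producing RR > 1 for that organ — the lateralized-case analog.

What the generator does **not** emulate: real spatial dose distributions,
anatomy- or beam-specific correlations between organs, inter-organ dose
trade-offs, breathing motion, or planning-system noise. Passing tests
therefore demonstrate correctness of the models and pipeline and the
qualitative proton-vs-photon effect under dominance, not clinical risk
magnitudes for any real cohort. Esophagus risk magnitudes in particular sit
near the LQ competition model's attainable maximum (α₁/(α₂·e) ≈ 0.2% for
the esophagus row), well below some published clinical figures.

## Numerical choices

* Volume fractions must sum to 1 within 1e-6; already-normalized input
  passes through un-rescaled so file round trips stay bit-identical.
  CSVs are written with 17 significant digits and read with round-trip
  float parsing.
* The plateau RED uses expm1 for accuracy at small α′D; the α₂ → 0 limit
  recovers the linear scenario to 1e-4 at α₂ scaled by 1e-6.
* Exact signed-rank distribution: counts accumulate in float64, exact for
  n ≤ 25 (counts ≤ 2²⁵ are far below 2⁵³).
* Degenerate inputs fail loudly: empty DVHs, zero organ volume, unknown
  organ labels, non-monotone cumulative volumes, male patients with breast
  DVHs, and photon-OED-zero ratios all raise typed errors naming the record.

## Default problem sizes

The test suite and acceptance script run the full default cohort (23
patients, ~80-bin DVHs, 5 organs, both modalities), 1000 random DVHs of up
to 200 bins for oracle-equivalence checks, exhaustive signed-rank
enumeration to n = 12, and a 200-patient cohort for population-fidelity
checks — a few seconds end to end on one core.
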