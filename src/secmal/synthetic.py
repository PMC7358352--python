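"""Seeded generator of paired proton/photon DVH cohorts.

No patient data ship with the package; this module emulates the statistical
structure of a 23-patient mediastinal-lymphoma cohort (16 female, 7 male;
prescription 20-39.6 Gy(RBE), mode 36; 10-22 fractions, mode 18; 1.8-2.0
Gy(RBE) per fraction) so every pipeline stage can be exercised with known
ground truth.

Each organ DVH is a three-component mixture, discretized to a fixed 0.5 Gy
bin grid from 0 to the prescription dose:

* a zero-dose mass (spared volume),
* an exponential low-dose tail (out-of-field scatter bath; photon tails are
  longer and heavier than proton tails),
* a near-prescription plateau mass (in-field volume of organs adjacent to
  the target).

Per-patient jitter (tail-length scale, mass shifts, plateau position) is
drawn once per organ and applied to *both* modalities, so the photon DVH
stochastically dominates the proton DVH for every non-adversarial organ by
construction — a dominance-repair step caps the proton tail weight at the
photon tail weight, moving any excess into the proton zero-dose mass.
A configurable fraction of patients is made *adversarial*: the resolved
mixture parameters of one organ (right breast or esophagus) are swapped
between modalities, reproducing lateralized cases whose proton dose to that
organ exceeds the photon dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh_io import (
    DVH_COLUMNS,
    FEMALE_ONLY_ORGANS,
    ORGANS,
    DifferentialDVH,
    PatientPair,
    PlanDose,
)
from .errors import DVHValidationError, SecmalError

MALE_ORGANS = tuple(o for o in ORGANS if o not in FEMALE_ONLY_ORGANS)

#: Organs an adversarial (lateralized) case may affect.
ADVERSARIAL_ORGANS = ("breast_right", "esophagus")


@dataclass(frozen=True)
class OrganMixture:
    """Mixture parameters of one organ/modality DVH.

    ``zero_mass`` + ``plateau_mass`` <= 1; the remainder is the exponential
    tail with mean ``tail_mean_gy``.
    """

    zero_mass: float
    tail_mean_gy: float
    plateau_mass: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_mass <= 1.0 or not 0.0 <= self.plateau_mass <= 1.0:
            raise DVHValidationError("mixture masses must lie in [0, 1]")
        if self.zero_mass + self.plateau_mass > 1.0 + 1e-12:
            raise DVHValidationError("zero and plateau masses exceed total volume")
        if self.tail_mean_gy < 0:
            raise DVHValidationError("tail mean must be >= 0")

    @property
    def tail_mass(self) -> float:
        return max(0.0, 1.0 - self.zero_mass - self.plateau_mass)


#: Photon ("butterfly" IMRT) defaults: broad scatter bath across the thorax,
#: sizeable in-field esophagus volume, left breast hotter than right (beam
#: weighting spares the right side less consistently than protons do).
PHOTON_MIXTURES: dict[str, OrganMixture] = {
    "lung_right": OrganMixture(0.15, 8.0, 0.08),
    "lung_left": OrganMixture(0.15, 8.0, 0.08),
    "breast_right": OrganMixture(0.35, 4.0, 0.01),
    "breast_left": OrganMixture(0.20, 6.0, 0.02),
    "esophagus": OrganMixture(0.05, 9.0, 0.45),
}

#: Proton (active scanning) defaults: sharply reduced out-of-field dose,
#: similar in-field esophagus plateau (the target wraps around it).
PROTON_MIXTURES: dict[str, OrganMixture] = {
    "lung_right": OrganMixture(0.50, 4.0, 0.06),
    "lung_left": OrganMixture(0.50, 4.0, 0.06),
    "breast_right": OrganMixture(0.75, 3.0, 0.005),
    "breast_left": OrganMixture(0.60, 4.0, 0.01),
    # same tail length as the photon plan, less mass everywhere: the target
    # wraps around the esophagus, so protons spare it by volume, not range
    "esophagus": OrganMixture(0.25, 9.0, 0.34),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator parameters (defaults mirror the study design)."""

    n_patients: int = 23
    n_female: int = 16
    seed: int = 42
    prescription_range: tuple[float, float] = (20.0, 39.6)  # Gy(RBE)
    prescription_mode: float = 36.0
    fractions_range: tuple[int, int] = (10, 22)
    fractions_mode: int = 18
    dose_per_fraction_range: tuple[float, float] = (1.8, 2.0)  # Gy(RBE)
    adversarial_fraction: float = 2.0 / 23.0
    photon_mixtures: Mapping[str, OrganMixture] = field(
        default_factory=lambda: dict(PHOTON_MIXTURES)
    )
    proton_mixtures: Mapping[str, OrganMixture] = field(
        default_factory=lambda: dict(PROTON_MIXTURES)
    )
    bin_width_gy: float = 0.5
    plateau_sigma_gy: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_female <= self.n_patients or self.n_patients < 1:
            raise SecmalError("need 0 <= n_female <= n_patients and n_patients >= 1")
        if not 0.0 <= self.adversarial_fraction <= 1.0:
            raise SecmalError("adversarial_fraction must lie in [0, 1]")
        for lo, hi in (
            self.prescription_range,
            self.fractions_range,
            self.dose_per_fraction_range,
        ):
            if lo <= 0 or hi < lo:
                raise SecmalError("ranges must be positive with low <= high")
        if not self.fractions_range[0] <= self.fractions_mode <= self.fractions_range[1]:
            raise SecmalError("fractions_mode must lie inside fractions_range")
        if self.bin_width_gy <= 0 or self.plateau_sigma_gy <= 0:
            raise SecmalError("bin width and plateau sigma must be > 0")


@dataclass(frozen=True)
class PatientGroundTruth:
    """Everything drawn for one generated patient (test-oracle bookkeeping)."""

    patient_id: str
    sex: str
    adversarial: bool
    adversarial_organ: str | None
    prescription_dose: float
    n_fractions: int
    plateau_center_gy: Mapping[str, float]
    mixtures: Mapping[str, Mapping[str, OrganMixture]]  # organ -> modality -> params


@dataclass(frozen=True)
class GroundTruth:
    config: GeneratorConfig
    patients: tuple[PatientGroundTruth, ...]

    @property
    def adversarial_patients(self) -> list[PatientGroundTruth]:
        return [p for p in self.patients if p.adversarial]


# ---------------------------------------------------------------------------
# DVH discretization
# ---------------------------------------------------------------------------


def _discretize_mixture(
    organ: str,
    mixture: OrganMixture,
    prescription: float,
    plateau_center: float,
    bin_width: float,
    plateau_sigma: float,
) -> DifferentialDVH:
    """Deterministically discretize a mixture onto the fixed bin grid.

    Tail mass beyond the prescription dose is lumped into the top bin; the
    plateau is a truncated normal around ``plateau_center``. Zero-fraction
    bins are dropped; a pure zero-dose organ collapses to a single bin.
    """
    n_bins = max(1, int(np.ceil(prescription / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2.0

    fractions = np.zeros(n_bins + 1)  # index 0 = zero-dose bin
    fractions[0] = mixture.zero_mass

    if mixture.tail_mass > 0 and mixture.tail_mean_gy > 0:
        decay = np.exp(-edges / mixture.tail_mean_gy)
        tail = decay[:-1] - decay[1:]
        tail[-1] += decay[-1]  # residual mass beyond the grid
        fractions[1:] += mixture.tail_mass * tail
    elif mixture.tail_mass > 0:
        fractions[0] += mixture.tail_mass  # zero-length tail degenerates to 0 Gy

    if mixture.plateau_mass > 0:
        cdf = stats.norm.cdf(edges, loc=plateau_center, scale=plateau_sigma)
        plateau = np.diff(cdf)
        plateau[0] += cdf[0]  # truncate below 0
        plateau[-1] += 1.0 - cdf[-1]  # truncate above the grid
        fractions[1:] += mixture.plateau_mass * plateau

    doses = np.concatenate(([0.0], centers))
    keep = fractions > 0
    return DifferentialDVH.normalized(organ, doses[keep], fractions[keep])


def sample_plan(
    organs: Sequence[str],
    modality: str,
    prescription: float,
    n_fractions: int,
    mixtures: Mapping[str, OrganMixture],
    plateau_centers: Mapping[str, float],
    bin_width: float = 0.5,
    plateau_sigma: float = 1.0,
) -> PlanDose:
    """Build one modality's plan from fully resolved mixture parameters.

    Deterministic: all randomness (jitter, adversarial swaps) is resolved by
    :func:`generate_cohort` before this is called, because per-patient jitter
    must be shared between the proton and photon plan of one patient.
    """
    if not organs:
        raise DVHValidationError("empty organ set")
    dvhs = {
        organ: _discretize_mixture(
            organ,
            mixtures[organ],
            prescription,
            plateau_centers[organ],
            bin_width,
            plateau_sigma,
        )
        for organ in organs
    }
    return PlanDose(modality, n_fractions, prescription, dvhs)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_fractionation(config: GeneratorConfig, rng: np.random.Generator):
    lo, hi = config.fractions_range
    if rng.random() < 0.6:
        n = config.fractions_mode
    else:
        n = int(round(rng.triangular(lo, config.fractions_mode, hi)))
        n = int(np.clip(n, lo, hi))
    d_lo, d_hi = config.dose_per_fraction_range
    dpf = d_hi if rng.random() < 0.7 else rng.uniform(d_lo, d_hi)
    prescription = float(np.clip(n * dpf, *config.prescription_range))
    return prescription, n


def _resolve_mixtures(
    config: GeneratorConfig, organ: str, rng: np.random.Generator
) -> dict[str, OrganMixture]:
    """Jitter the base mixtures of one organ, shared across modalities, and
    repair any tail-weight inversion so photon >= proton dominance holds."""
    tail_scale = float(np.exp(rng.normal(0.0, 0.2)))
    zero_shift = float(rng.normal(0.0, 0.04))
    plateau_scale = float(np.exp(rng.normal(0.0, 0.25)))

    resolved = {}
    for modality, base in (
        ("photon", config.photon_mixtures[organ]),
        ("proton", config.proton_mixtures[organ]),
    ):
        zero = float(np.clip(base.zero_mass + zero_shift, 0.0, 0.97))
        plateau = min(base.plateau_mass * plateau_scale, max(0.0, 0.99 - zero))
        resolved[modality] = OrganMixture(zero, base.tail_mean_gy * tail_scale, plateau)

    excess = resolved["proton"].tail_mass - resolved["photon"].tail_mass
    if excess > 0:
        resolved["proton"] = replace(
            resolved["proton"], zero_mass=resolved["proton"].zero_mass + excess
        )
    return resolved


def generate_cohort(config: GeneratorConfig) -> tuple[list[PatientPair], GroundTruth]:
    """Generate a paired cohort plus full ground truth.

    The first ``n_female`` patients are female (all five organs); male
    patients carry lungs and esophagus only. Each patient is adversarial
    with probability ``adversarial_fraction``; the affected organ's resolved
    mixtures are swapped between modalities. Randomness comes from
    per-patient substreams seeded by (seed, patient index), so adding a
    patient never perturbs earlier ones.
    """
    pairs: list[PatientPair] = []
    records: list[PatientGroundTruth] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        patient_id = f"P{i + 1:02d}"
        sex = "female" if i < config.n_female else "male"
        organs = ORGANS if sex == "female" else MALE_ORGANS

        prescription, n_fractions = _draw_fractionation(config, rng)

        adversarial = rng.random() < config.adversarial_fraction
        if adversarial:
            if sex == "female":
                adversarial_organ = ADVERSARIAL_ORGANS[int(rng.random() < 0.5)]
            else:
                adversarial_organ = "esophagus"
        else:
            adversarial_organ = None

        mixtures: dict[str, dict[str, OrganMixture]] = {}
        plateau_centers: dict[str, float] = {}
        for organ in organs:
            resolved = _resolve_mixtures(config, organ, rng)
            plateau_centers[organ] = float(rng.uniform(0.90, 0.98) * prescription)
            if organ == adversarial_organ:
                resolved = {"photon": resolved["proton"], "proton": resolved["photon"]}
            mixtures[organ] = resolved

        plans = {
            modality: sample_plan(
                organs,
                modality,
                prescription,
                n_fractions,
                {o: mixtures[o][modality] for o in organs},
                plateau_centers,
                config.bin_width_gy,
                config.plateau_sigma_gy,
            )
            for modality in ("proton", "photon")
        }
        pairs.append(PatientPair(patient_id, sex, plans["proton"], plans["photon"]))
        records.append(
            PatientGroundTruth(
                patient_id,
                sex,
                adversarial,
                adversarial_organ,
                prescription,
                n_fractions,
                plateau_centers,
                mixtures,
            )
        )
    return pairs, GroundTruth(config, tuple(records))


def export_cohort(pairs: Sequence[PatientPair], path) -> None:
    """Write a cohort in the differential DVH CSV dialect.

    Round-trips losslessly through :func:`secmal.dvh_io.read_dvh_table`
    (floats are written with 17 significant digits) and is byte-identical
    across runs for a fixed cohort.
    """
    if not pairs:
        raise SecmalError("refusing to export an empty cohort")
    rows = []
    for pair in pairs:
        for plan in (pair.proton, pair.photon):
            for organ in sorted(plan.dvhs):
                dvh = plan.dvhs[organ]
                for dose, fraction in zip(dvh.doses, dvh.volume_fractions):
                    rows.append(
                        (
                            pair.patient_id,
                            pair.sex,
                            plan.modality,
                            organ,
                            plan.n_fractions,
                            plan.prescription_dose,
                            dose,
                            fraction,
                        )
                    )
    df = pd.DataFrame(rows, columns=list(DVH_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")
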