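"""Dose-volume histogram containers and plain-text I/O.

DVHs are held internally in *differential* form with dimensionless volume
fractions: the risk models are volume-weighted averages over dose bins, so
absolute organ volumes (cc) are irrelevant once fractions are normalized.
Cumulative exports from a treatment planning system are converted on read.

The on-disk dialect is a flat CSV with one row per dose bin:

    patient_id, sex, modality, organ, n_fractions, prescription_dose_gy,
    dose_gy, volume

where ``volume`` is either cumulative cc (volume receiving >= dose) or a
differential volume fraction, selected by the reader's ``dialect`` flag.
Rows belonging to one (patient, modality, organ) must be contiguous and
dose-sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateOrganError,
    DVHValidationError,
    FormatError,
    PairingError,
    SecmalError,
    UnknownOrganError,
)

#: Supported organ-at-risk labels. Risk coefficients exist only for these;
#: anything else is an error, not a warning.
ORGANS = ("lung_right", "lung_left", "breast_right", "breast_left", "esophagus")

#: Bilateral organ groups used for combined (left+right summed) risk reporting.
ORGAN_GROUPS = {
    "lung": ("lung_right", "lung_left"),
    "breast": ("breast_right", "breast_left"),
}

MODALITIES = ("proton", "photon")
SEXES = ("female", "male")

#: Organs only present for female patients.
FEMALE_ONLY_ORGANS = frozenset({"breast_right", "breast_left"})

#: Tolerance on the sum of normalized volume fractions.
VOLUME_SUM_TOL = 1e-6

#: Required columns of the DVH CSV dialect, in canonical order.
DVH_COLUMNS = (
    "patient_id",
    "sex",
    "modality",
    "organ",
    "n_fractions",
    "prescription_dose_gy",
    "dose_gy",
    "volume",
)

#: Columns of the results CSV dialect.
RESULT_COLUMNS = ("patient_id", "organ", "modality", "model", "quantity", "value")

RESULT_MODELS = ("dasu", "schneider_linear", "schneider_linexp", "schneider_plateau")
RESULT_QUANTITIES = ("total_risk", "fatal_risk", "oed_gy", "relative_risk")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DVHBin:
    """One differential DVH bin: absolute dose in Gy(RBE) at the bin center
    and the dimensionless fraction of organ volume receiving it."""

    dose: float
    volume_fraction: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise DVHValidationError(f"bin dose must be >= 0, got {self.dose}")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise DVHValidationError(
                f"volume fraction must be in [0, 1], got {self.volume_fraction}"
            )


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential dose-volume histogram of one organ.

    Parameters
    ----------
    organ
        One of :data:`ORGANS`.
    doses
        Bin-center doses in Gy(RBE), strictly increasing, all >= 0.
    volume_fractions
        Fraction of organ volume per bin; must sum to 1 within
        :data:`VOLUME_SUM_TOL`.
    """

    organ: str
    doses: np.ndarray
    volume_fractions: np.ndarray

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise UnknownOrganError(self.organ)
        doses = np.asarray(self.doses, dtype=float)
        fractions = np.asarray(self.volume_fractions, dtype=float)
        if doses.ndim != 1 or fractions.shape != doses.shape:
            raise DVHValidationError("doses and volume_fractions must be matching 1-D arrays")
        if doses.size < 1:
            raise DVHValidationError(f"{self.organ}: a DVH needs at least one bin")
        if doses[0] < 0 or np.any(np.diff(doses) <= 0):
            raise DVHValidationError(
                f"{self.organ}: bin doses must be non-negative and strictly increasing"
            )
        if np.any(fractions < 0) or np.any(fractions > 1):
            raise DVHValidationError(f"{self.organ}: volume fractions must lie in [0, 1]")
        total = float(fractions.sum())
        if abs(total - 1.0) > VOLUME_SUM_TOL:
            raise DVHValidationError(
                f"{self.organ}: volume fractions sum to {total!r}, expected 1"
            )
        doses.setflags(write=False)
        fractions.setflags(write=False)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "volume_fractions", fractions)

    @classmethod
    def normalized(
        cls, organ: str, doses: Iterable[float], volumes: Iterable[float]
    ) -> "DifferentialDVH":
        """Build a DVH from raw per-bin volumes, rescaling them to sum to 1."""
        volumes = np.asarray(list(volumes), dtype=float)
        total = volumes.sum()
        if total <= 0:
            raise DegenerateOrganError(f"{organ}: total volume is zero")
        if abs(total - 1.0) > VOLUME_SUM_TOL:  # already-normalized input passes through
            volumes = volumes / total
        return cls(organ, np.asarray(list(doses), dtype=float), volumes)

    @classmethod
    def from_bins(cls, organ: str, bins: Iterable[DVHBin]) -> "DifferentialDVH":
        bins = list(bins)
        return cls(
            organ,
            np.array([b.dose for b in bins]),
            np.array([b.volume_fraction for b in bins]),
        )

    @property
    def bins(self) -> tuple[DVHBin, ...]:
        return tuple(
            DVHBin(float(d), float(v))
            for d, v in zip(self.doses, self.volume_fractions)
        )

    @property
    def max_dose(self) -> float:
        return float(self.doses[-1])


@dataclass(frozen=True)
class PlanDose:
    """One modality's full DVH set plus fractionation metadata."""

    modality: str
    n_fractions: int
    prescription_dose: float  # Gy(RBE)
    dvhs: Mapping[str, DifferentialDVH]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DVHValidationError(f"unknown modality {self.modality!r}")
        if int(self.n_fractions) < 1:
            raise DVHValidationError(f"n_fractions must be >= 1, got {self.n_fractions}")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        if self.prescription_dose <= 0:
            raise DVHValidationError(
                f"prescription dose must be > 0, got {self.prescription_dose}"
            )
        for organ, dvh in self.dvhs.items():
            if dvh.organ != organ:
                raise DVHValidationError(
                    f"DVH stored under key {organ!r} is labelled {dvh.organ!r}"
                )
        object.__setattr__(self, "dvhs", dict(self.dvhs))

    @property
    def organs(self) -> frozenset[str]:
        return frozenset(self.dvhs)


@dataclass(frozen=True)
class PatientPair:
    """Matched proton and photon plans for one patient."""

    patient_id: str
    sex: str
    proton: PlanDose
    photon: PlanDose

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DVHValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.proton.modality != "proton" or self.photon.modality != "photon":
            raise PairingError(f"{self.patient_id}: plans assigned to the wrong modality slots")
        if self.proton.organs != self.photon.organs:
            missing = self.proton.organs ^ self.photon.organs
            raise PairingError(
                f"{self.patient_id}: organ sets differ between modalities "
                f"({', '.join(sorted(missing))})"
            )
        if self.sex == "male" and self.proton.organs & FEMALE_ONLY_ORGANS:
            raise DVHValidationError(
                f"{self.patient_id}: breast DVHs present for a male patient"
            )

    @property
    def organs(self) -> frozenset[str]:
        return self.proton.organs


# ---------------------------------------------------------------------------
# cumulative <-> differential conversion
# ---------------------------------------------------------------------------


def cumulative_to_differential(
    organ: str, doses: Iterable[float], cum_volumes: Iterable[float]
) -> DifferentialDVH:
    """Convert a cumulative DVH (volume receiving >= dose) to differential form.

    Bin ``i`` (below the last grid point) receives volume fraction
    ``(V[i] - V[i+1]) / V[0]`` at the interval midpoint; the residual volume
    at the last grid point is kept as a terminal bin at that dose.
    Zero-fraction bins are dropped.
    """
    doses = np.asarray(list(doses), dtype=float)
    cum = np.asarray(list(cum_volumes), dtype=float)
    if doses.shape != cum.shape or doses.ndim != 1 or doses.size < 1:
        raise DVHValidationError(f"{organ}: dose and volume grids must be matching 1-D arrays")
    if np.any(np.diff(doses) <= 0):
        raise DVHValidationError(f"{organ}: cumulative dose grid must be strictly increasing")
    if cum[-1] < 0 or np.any(np.diff(cum) > 0):
        raise DVHValidationError(
            f"{organ}: cumulative volumes must be non-increasing and end >= 0"
        )
    if cum[0] <= 0:
        raise DegenerateOrganError(f"{organ}: organ volume at zero dose is zero")

    mid = (doses[:-1] + doses[1:]) / 2.0
    frac = -np.diff(cum) / cum[0]
    bin_doses = np.append(mid, doses[-1])
    bin_fracs = np.append(frac, cum[-1] / cum[0])
    keep = bin_fracs > 0
    if not keep.any():  # unreachable while cum[0] > 0, kept for safety
        raise DegenerateOrganError(f"{organ}: no volume in any bin")
    return DifferentialDVH.normalized(organ, bin_doses[keep], bin_fracs[keep])


def differential_to_cumulative(dvh: DifferentialDVH) -> tuple[np.ndarray, np.ndarray]:
    """Express a differential DVH as a cumulative one on its own bin grid.

    Returns ``(doses, cum_fractions)`` where ``cum_fractions[i]`` is the
    volume fraction receiving at least ``doses[i]``. Feeding the result back
    through :func:`cumulative_to_differential` reproduces the volume
    fractions exactly (bin doses move to interval midpoints).
    """
    cum = np.cumsum(dvh.volume_fractions[::-1])[::-1]
    return dvh.doses.copy(), cum


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _unique(series: pd.Series, what: str, context: str):
    values = series.unique()
    if len(values) != 1:
        raise DVHValidationError(f"{context}: inconsistent {what}: {list(values)!r}")
    return values[0]


def read_dvh_table(path, dialect: str) -> list[PatientPair]:
    """Read a DVH CSV file into validated :class:`PatientPair` records.

    ``dialect`` selects how the ``volume`` column is interpreted:
    ``"cumulative"`` (cc at >= dose, converted via
    :func:`cumulative_to_differential`) or ``"differential"`` (per-bin
    fractions, normalized to sum to 1).
    """
    if dialect not in ("cumulative", "differential"):
        raise ValueError(f"dialect must be 'cumulative' or 'differential', got {dialect!r}")
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    for column in DVH_COLUMNS:
        if column not in df.columns:
            raise FormatError(f"missing required column {column!r}")

    # (patient, modality, organ) blocks must be contiguous
    key = df[["patient_id", "modality", "organ"]].astype(str).agg("|".join, axis=1)
    block_starts = key.ne(key.shift())
    seen: set[str] = set()
    for k in key[block_starts]:
        if k in seen:
            raise FormatError(
                f"rows for ({k.replace('|', ', ')}) are not contiguous in the file"
            )
        seen.add(k)

    pairs: list[PatientPair] = []
    for patient_id, pat_df in df.groupby("patient_id", sort=False):
        sex = _unique(pat_df["sex"], "sex", f"patient {patient_id}")
        if sex not in SEXES:
            raise DVHValidationError(f"patient {patient_id}: unknown sex {sex!r}")
        plans: dict[str, PlanDose] = {}
        for modality, mod_df in pat_df.groupby("modality", sort=False):
            if modality not in MODALITIES:
                raise DVHValidationError(
                    f"patient {patient_id}: unknown modality {modality!r}"
                )
            context = f"patient {patient_id}, {modality}"
            n_fractions = int(_unique(mod_df["n_fractions"], "n_fractions", context))
            prescription = float(
                _unique(mod_df["prescription_dose_gy"], "prescription dose", context)
            )
            dvhs: dict[str, DifferentialDVH] = {}
            for organ, organ_df in mod_df.groupby("organ", sort=False):
                if organ not in ORGANS:
                    raise UnknownOrganError(f"{context}: unknown organ {organ!r}")
                doses = organ_df["dose_gy"].to_numpy(dtype=float)
                volumes = organ_df["volume"].to_numpy(dtype=float)
                if np.any(np.diff(doses) <= 0):
                    raise DVHValidationError(
                        f"{context}, {organ}: doses must be strictly increasing"
                    )
                if dialect == "cumulative":
                    if np.any(np.diff(volumes) > 0):
                        raise DVHValidationError(
                            f"{context}, {organ}: cumulative volume increases with dose"
                        )
                    dvhs[organ] = cumulative_to_differential(organ, doses, volumes)
                else:
                    dvhs[organ] = DifferentialDVH.normalized(organ, doses, volumes)
            plans[modality] = PlanDose(modality, n_fractions, prescription, dvhs)
        if set(plans) != set(MODALITIES):
            raise PairingError(
                f"patient {patient_id}: need both proton and photon plans, "
                f"found {sorted(plans)}"
            )
        pairs.append(PatientPair(str(patient_id), sex, plans["proton"], plans["photon"]))
    return pairs


def write_results(results, path) -> None:
    """Write cohort result records to the results CSV dialect.

    ``results`` is a DataFrame or iterable of mappings with the columns
    ``patient_id, organ, modality, model, quantity, value``. Values survive a
    read/write round trip bit-identically (written with 17 significant
    digits).
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    if df.empty:
        raise SecmalError("refusing to write an empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results records lack columns: {missing}")
    df = df[list(RESULT_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results file lacks columns: {missing}")
    return df
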