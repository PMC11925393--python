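"""Clinic configuration: resources, service-time distributions, operating window.

Defaults describe a high-volume breast imaging center: check-in stops at 9.5 h
after opening, the clinic nominally closes at 10 h, a 10% no-show rate, and an
average of 60 checked-in patients per weekday of whom 42% receive a screening
mammogram.  Service times are truncated normal distributions (mean, SD in
hours).  Staff, rooms, technologists and radiologists are shared, capacity-
limited resources.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a clinic or scenario configuration is invalid."""


# Patient types flowing through the clinic.
SCREENING_MAMMO = "screening_mammo"
SCREENING_US = "screening_us"
DIAGNOSTIC = "diagnostic"
BIOPSY_STEREO = "biopsy_stereo"
BIOPSY_US = "biopsy_us"
BIOPSY_MR = "biopsy_mr"

PATIENT_TYPES = (
    SCREENING_MAMMO,
    SCREENING_US,
    DIAGNOSTIC,
    BIOPSY_STEREO,
    BIOPSY_US,
    BIOPSY_MR,
)

# Resource pool names.
STAFF = "staff"
CONSENT = "consent"
DRESSING = "dressing"
GOWNED_WAIT = "gowned_wait"
PUBLIC_WAIT = "public_wait"
MAMMO_TECH = "mammo_tech"
US_TECH = "us_tech"
RADIOLOGIST = "radiologist"


@dataclass(frozen=True)
class ServiceTimeSpec:
    """A truncated-normal service duration, in hours.

    Negative draws are rejected and resampled so the realized mean stays close
    to ``mean`` (clipping at zero would bias it upward less gracefully).
    """

    mean: float
    sd: float
    family: str = "normal_truncated"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ConfigurationError(f"service-time mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ConfigurationError(f"service-time sd must be >= 0, got {self.sd}")
        if self.family != "normal_truncated":
            raise ConfigurationError(f"unknown service-time family {self.family!r}")


@dataclass(frozen=True)
class ResourcePool:
    name: str
    capacity: int

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ConfigurationError(f"capacity of {self.name!r} must be >= 1")


def _default_resources() -> dict[str, int]:
    return {
        STAFF: 3,
        CONSENT: 1,
        DRESSING: 3,
        GOWNED_WAIT: 5,
        PUBLIC_WAIT: 20,
        MAMMO_TECH: 3,
        US_TECH: 2,
        RADIOLOGIST: 4,
    }


def _default_service_times() -> dict[str, ServiceTimeSpec]:
    return {
        "checkin": ServiceTimeSpec(0.05, 0.01),
        "public_wait_dwell": ServiceTimeSpec(0.17, 0.034),
        "consent": ServiceTimeSpec(0.17, 0.034),
        "dressing": ServiceTimeSpec(0.03, 0.006),
        "gowned_wait_dwell": ServiceTimeSpec(0.017, 0.0034),
        "ai_assessment": ServiceTimeSpec(0.25, 0.05),
        "screening_mammo": ServiceTimeSpec(0.17, 0.034),
        "screening_us": ServiceTimeSpec(0.25, 0.05),
        "diagnostic_mammo": ServiceTimeSpec(0.417, 0.0834),
        "diagnostic_us": ServiceTimeSpec(0.417, 0.0834),
        "diagnostic_review": ServiceTimeSpec(0.083, 0.017),
        "biopsy_stereo": ServiceTimeSpec(0.75, 0.15),
        "biopsy_us": ServiceTimeSpec(0.75, 0.15),
        "biopsy_mr": ServiceTimeSpec(0.5, 0.1),
    }


def _default_type_mix() -> dict[str, float]:
    # Screening mammography share (0.42) is calibrated to observed volume; the
    # split of the remainder across screening US / diagnostic / biopsy is a
    # documented placeholder (the true hourly type mix is not modelled).
    return {
        SCREENING_MAMMO: 0.42,
        SCREENING_US: 0.10,
        DIAGNOSTIC: 0.38,
        "biopsy": 0.10,
    }


@dataclass
class ClinicConfig:
    """All clinic-level parameters.

    Times are hours from clinic opening; ``checkin_cutoff`` is when patient
    check-in stops (9.5 h) and ``close`` the nominal closing time (10 h);
    service continues past close until every checked-in patient completes.
    ``expected_checked_in_per_day`` calibrates arrival volume: it is the mean
    number of patients who actually check in (no-shows excluded).
    """

    checkin_cutoff: float = 9.5
    close: float = 10.0
    no_show_rate: float = 0.10
    expected_checked_in_per_day: float = 60.0
    type_mix: dict[str, float] = field(default_factory=_default_type_mix)
    biopsy_subtype_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # stereo/US/MR, placeholder
    same_day_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)  # mammo+US / mammo / US
    scheduled_diagnostic_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)  # placeholder, mirrors same-day
    followup_delay_mean_days: float = 20.0
    followup_delay_sd_days: float = 4.0
    followup_slot_multiplier: float = 0.67
    resources: dict[str, int] = field(default_factory=_default_resources)
    service_times: dict[str, ServiceTimeSpec] = field(default_factory=_default_service_times)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def expected_screening_per_day(self) -> float:
        """Mean number of screening-mammography patients who arrive per day."""
        return self.type_mix[SCREENING_MAMMO] * self.expected_checked_in_per_day

    @property
    def followup_slot_count(self) -> int:
        """Upper bound of the discrete-uniform follow-up slot draw."""
        return int(round(self.followup_slot_multiplier * self.expected_checked_in_per_day))

    def validate(self) -> None:
        if not 0 <= self.no_show_rate < 1:
            raise ConfigurationError("no_show_rate must be in [0, 1)")
        if not self.checkin_cutoff < self.close:
            raise ConfigurationError("checkin_cutoff must precede close")
        if self.expected_checked_in_per_day <= 0:
            raise ConfigurationError("expected_checked_in_per_day must be > 0")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("type_mix fractions must sum to 1")
        for mix, label in (
            (self.same_day_mix, "same_day_mix"),
            (self.scheduled_diagnostic_mix, "scheduled_diagnostic_mix"),
            (self.biopsy_subtype_mix, "biopsy_subtype_mix"),
        ):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigurationError(f"{label} must sum to 1")
        for name, cap in self.resources.items():
            ResourcePool(name, cap)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["service_times"] = {
            k: {"mean": v["mean"], "sd": v["sd"], "family": v["family"]}
            for k, v in d["service_times"].items()
        }
        for key in ("biopsy_subtype_mix", "same_day_mix", "scheduled_diagnostic_mix"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClinicConfig":
        d = dict(d)
        if "service_times" in d:
            d["service_times"] = {
                k: v if isinstance(v, ServiceTimeSpec) else ServiceTimeSpec(**v)
                for k, v in d["service_times"].items()
            }
        for key in ("biopsy_subtype_mix", "same_day_mix", "scheduled_diagnostic_mix"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ClinicConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)


def default_clinic_config() -> ClinicConfig:
    return ClinicConfig()
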