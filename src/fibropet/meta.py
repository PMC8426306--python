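"""Per-scan study metadata: who was scanned, when, with what tracer and dose."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77

#: Study arms of the bleomycin model.
GROUPS = ("NaCl", "BLM", "BLM+pirfenidone", "BLM+nintedanib")

#: Tracers and their default injected dose (MBq) and uptake delay (minutes)
#: between injection and acquisition start.
TRACER_DOSE_MBQ = {"FDG": 5.0, "FMISO": 10.0}
TRACER_UPTAKE_MIN = {"FDG": 20.0, "FMISO": 120.0}


@dataclass(frozen=True)
class ScanMeta:
    """Provenance record for a single PET acquisition.

    ``day`` is the actual study day of the acquisition (FDG and FMISO are
    acquired on consecutive days; see the longitudinal module for the
    nominal-day pairing convention).
    """

    animal_id: str
    group: str
    day: int
    tracer: str
    dose_mbq: float
    t_injection: datetime
    t_scan: datetime
    weight_g: float = 20.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.tracer not in TRACER_DOSE_MBQ:
            raise ValueError(f"unknown tracer {self.tracer!r}; expected one of {sorted(TRACER_DOSE_MBQ)}")
        if self.dose_mbq <= 0:
            raise ValueError(f"injected dose must be positive, got {self.dose_mbq} MBq")
        if self.weight_g <= 0:
            raise ValueError(f"body weight must be positive, got {self.weight_g} g")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.t_scan < self.t_injection:
            raise ValueError(f"acquisition time {self.t_scan} precedes injection time {self.t_injection}")

    @property
    def uptake_minutes(self) -> float:
        """Minutes elapsed between injection and acquisition start."""
        return (self.t_scan - self.t_injection).total_seconds() / 60.0


def default_scan_meta(animal_id: str, group: str, day: int, tracer: str,
                      weight_g: float = 20.0,
                      study_epoch: datetime | None = None) -> ScanMeta:
    """Build a ScanMeta with the study's default dose and uptake delay.

    Injection happens at 09:00 on the scan day relative to ``study_epoch``
    (day 0 at midnight); acquisition follows after the tracer's uptake delay
    (20 min FDG, 120 min FMISO).
    """
    epoch = study_epoch or datetime(2020, 1, 1)
    t_inj = epoch + timedelta(days=int(day), hours=9)
    t_scan = t_inj + timedelta(minutes=TRACER_UPTAKE_MIN[tracer])
    return ScanMeta(
        animal_id=animal_id, group=group, day=int(day), tracer=tracer,
        dose_mbq=TRACER_DOSE_MBQ[tracer], t_injection=t_inj, t_scan=t_scan,
        weight_g=weight_g,
    )
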