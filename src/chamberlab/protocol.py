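"""Study-design layer: diet library, crossover schedule, eligibility and
compliance rules.

The protocol has seven dietary chamber conditions: energy balance (EB),
24-hour fasting (FAST) and five 200%-overfeeding diets of differing
macronutrient split (SOF standard, LPF low-protein, FNP high-fat/
normal-protein, HPF high-fat/high-protein, CNP high-carbohydrate/
normal-protein). An initial eucaloric calibration chamber measures 24-hour
EE; that measurement sets the intake for the EB chamber, whose measured EE
then anchors the 200% prescriptions. Intervention chambers run in
randomized order separated by washout days on a weight-maintaining diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DIET_NAMES",
    "DietPrescription",
    "Participant",
    "ChamberSession",
    "ChamberSchedule",
    "build_diet_library",
    "calibrate_energy_balance",
    "prescribe_intake",
    "randomize_schedule",
    "eligibility_filter",
    "compliance_filter",
    "weight_stability_cv",
]

DIET_NAMES = ("EB", "FAST", "SOF", "LPF", "FNP", "HPF", "CNP")
OVERFEEDING_DIETS = ("SOF", "LPF", "FNP", "HPF", "CNP")

# Default macronutrient energy fractions (carb, fat, protein). The study's
# exact splits are not public; these are synthetic defaults capturing the
# design intent (LPF protein at 3%, FNP/HPF fat-heavy, CNP carb-heavy) and
# are overridable via build_diet_library(config=...).
_DEFAULT_COMPOSITION = {
    "EB": (0.50, 0.30, 0.20, 1.0),
    "FAST": (0.0, 0.0, 0.0, 0.0),
    "SOF": (0.50, 0.30, 0.20, 2.0),
    "LPF": (0.51, 0.46, 0.03, 2.0),
    "FNP": (0.20, 0.60, 0.20, 2.0),
    "HPF": (0.25, 0.45, 0.30, 2.0),
    "CNP": (0.75, 0.05, 0.20, 2.0),
}

# OGTT exclusion thresholds, mg/dL.
IMPAIRED_FASTING = 100.0
IMPAIRED_2H = 140.0
T2D_FASTING = 126.0
T2D_2H = 200.0

COMPLIANCE_MIN_FRACTION = 0.95
MIN_WASHOUT_DAYS = 3


class DietValidationError(ValueError):
    """A diet's macronutrient fractions or multiplier are malformed."""


@dataclass(frozen=True)
class DietPrescription:
    """One chamber condition: macronutrient energy split and intake multiplier.

    ``energy_multiplier`` scales the participant's EB 24-hour EE: 0 for
    fasting, 1 for energy balance, 2 for the overfeeding diets.
    """

    name: str
    carb_frac: float
    fat_frac: float
    prot_frac: float
    energy_multiplier: float

    def __post_init__(self) -> None:
        if self.name not in DIET_NAMES:
            raise DietValidationError(f"unknown diet name {self.name!r}")
        fracs = (self.carb_frac, self.fat_frac, self.prot_frac)
        if any(f < 0 or f > 1 for f in fracs):
            raise DietValidationError(f"{self.name}: fractions must lie in [0, 1]")
        if self.energy_multiplier < 0:
            raise DietValidationError(f"{self.name}: energy multiplier must be >= 0")
        if self.name == "FAST":
            if self.energy_multiplier != 0:
                raise DietValidationError("FAST: fasting means zero intake")
        elif abs(sum(fracs) - 1.0) > 1e-9:
            raise DietValidationError(
                f"{self.name}: macronutrient fractions sum to {sum(fracs):.6f}, not 1"
            )

    @property
    def is_fed(self) -> bool:
        return self.energy_multiplier > 0

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.carb_frac, self.fat_frac, self.prot_frac)


@dataclass
class Participant:
    id: str
    age: float
    sex: str
    race: str
    bmi: float
    weight_series: list[float]
    fasting_glucose: float
    glucose_2h: float

    def __post_init__(self) -> None:
        if not self.weight_series:
            raise ValueError(f"{self.id}: weight series must be nonempty")
        if self.fasting_glucose <= 0 or self.glucose_2h <= 0:
            raise ValueError(f"{self.id}: glucose values must be positive")


@dataclass
class ChamberSession:
    chamber_order: int
    diet: str
    prescribed_kcal: float
    washout_days_before: int
    start_day: int
    is_calibration: bool = False


@dataclass
class ChamberSchedule:
    """One participant's chamber sequence.

    ``calibration`` is the initial eucaloric session used only to measure
    24-hour EE; the seven analysis chambers follow, numbered 1..7 with EB
    always order 1 (its intake is the calibration measurement) and the six
    interventions in randomized order.
    """

    participant_id: str
    calibration: ChamberSession
    chambers: list[ChamberSession] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chambers)

    @property
    def sessions(self) -> list[ChamberSession]:
        """Physical sequence: calibration first, then analysis chambers."""
        return [self.calibration, *self.chambers]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "participant_id": self.participant_id,
                    "chamber_order": s.chamber_order,
                    "diet": s.diet,
                    "prescribed_kcal": s.prescribed_kcal,
                    "start_day": s.start_day,
                    "is_calibration": s.is_calibration,
                }
                for s in self.sessions
            ]
        )


def build_diet_library(config: dict | str | Path | None = None) -> list[DietPrescription]:
    """Construct all seven chamber conditions.

    ``config`` may be a mapping ``{name: (carb, fat, prot, multiplier)}`` or a
    path to a key-value text file with lines ``NAME carb fat prot multiplier``
    (``#`` comments allowed). Defaults cover every diet; a config may override
    a subset. Malformed fractions raise :class:`DietValidationError` naming
    the diet.
    """
    table = dict(_DEFAULT_COMPOSITION)
    if config is not None:
        if isinstance(config, (str, Path)):
            config = _read_diet_config(Path(config))
        for name, spec in config.items():
            table[name] = tuple(float(x) for x in spec)
    unknown = set(table) - set(DIET_NAMES)
    if unknown:
        raise DietValidationError(f"unknown diet names in config: {sorted(unknown)}")
    return [
        DietPrescription(name, *table[name])
        for name in DIET_NAMES
    ]


def _read_diet_config(path: Path) -> dict:
    out = {}
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise DietValidationError(
                f"diet config line needs 'NAME carb fat prot multiplier': {line!r}"
            )
        out[parts[0]] = tuple(float(x) for x in parts[1:])
    return out


def calibrate_energy_balance(first_chamber_ee: float) -> float:
    """Intake for the EB chamber: the measured 24-h EE of the first
    eucaloric chamber, passed through unchanged."""
    if first_chamber_ee <= 0:
        raise ValueError("measured 24-h EE must be positive")
    return float(first_chamber_ee)


def prescribe_intake(diet: DietPrescription, eb_ee: float) -> float:
    """Prescribed kcal/day for a chamber: energy_multiplier x EB 24-h EE
    (200% of energy needs for the overfeeding diets, zero for fasting)."""
    if eb_ee <= 0:
        raise ValueError("EB 24-h EE must be positive")
    return diet.energy_multiplier * eb_ee


def _fisher_yates(items: list, rng: np.random.Generator) -> list:
    """In-place seeded Fisher-Yates shuffle (returns the list)."""
    items = list(items)
    for i in range(len(items) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        items[i], items[j] = items[j], items[i]
    return items


def randomize_schedule(
    participant: Participant | str,
    diets: Sequence[DietPrescription],
    seed: int,
    *,
    eb_ee: float | None = None,
    washout_days: int = MIN_WASHOUT_DAYS,
) -> ChamberSchedule:
    """Build one participant's crossover schedule with seeded randomization.

    The calibration chamber and EB come first (in that fixed order); the
    remaining diets are permuted by a seeded Fisher-Yates shuffle, giving a
    uniform random intervention order that is reproducible per seed.
    ``eb_ee`` (the measured or simulated EB energy need, kcal/day) fills
    ``prescribed_kcal``; when unknown it is left as NaN to be filled after
    calibration.
    """
    if washout_days < MIN_WASHOUT_DAYS:
        raise ValueError(f"washout must be at least {MIN_WASHOUT_DAYS} days")
    pid = participant.id if isinstance(participant, Participant) else str(participant)
    by_name = {d.name: d for d in diets}
    if "EB" not in by_name:
        raise ValueError("diet list must include the EB calibration pair")
    interventions = [d for d in diets if d.name != "EB"]
    rng = np.random.default_rng(seed)
    order = _fisher_yates(interventions, rng)

    def kcal(d: DietPrescription) -> float:
        return prescribe_intake(d, eb_ee) if eb_ee is not None else float("nan")

    eb = by_name["EB"]
    calibration = ChamberSession(
        chamber_order=0, diet="EB", prescribed_kcal=kcal(eb),
        washout_days_before=0, start_day=0, is_calibration=True,
    )
    chambers = []
    day = washout_days + 1
    chambers.append(ChamberSession(1, "EB", kcal(eb), washout_days, day))
    for k, d in enumerate(order, start=2):
        day += washout_days + 1
        chambers.append(ChamberSession(k, d.name, kcal(d), washout_days, day))
    return ChamberSchedule(participant_id=pid, calibration=calibration, chambers=chambers)


def eligibility_filter(
    participants: Iterable[Participant],
) -> tuple[list[Participant], dict[str, str]]:
    """Apply the OGTT screening rule.

    Excludes type 2 diabetes (fasting >= 126 or 2-h >= 200 mg/dL) and
    impaired glucose regulation (fasting >= 100 or 2-h >= 140 mg/dL);
    returns retained participants and a reason per exclusion.
    """
    retained, reasons = [], {}
    for p in participants:
        if p.fasting_glucose >= T2D_FASTING or p.glucose_2h >= T2D_2H:
            reasons[p.id] = "type_2_diabetes"
        elif p.fasting_glucose >= IMPAIRED_FASTING or p.glucose_2h >= IMPAIRED_2H:
            reasons[p.id] = "impaired_glucose_regulation"
        else:
            retained.append(p)
    return retained, reasons


def compliance_filter(consumed_kcal: float, provided_kcal: float) -> bool:
    """True if the session is kept: > 95% of provided food consumed.

    Fasting chambers (nothing provided) are always kept.
    """
    if provided_kcal < 0:
        raise ValueError("provided kcal must be nonnegative")
    if provided_kcal == 0:
        return True
    return consumed_kcal / provided_kcal > COMPLIANCE_MIN_FRACTION


def weight_stability_cv(weight_series: Sequence[float]) -> float:
    """Percent coefficient of variation of a daily weight series."""
    w = np.asarray(weight_series, dtype=float)
    if w.size < 2:
        raise ValueError("weight CV needs at least two measurements")
    return 100.0 * float(np.std(w, ddof=1) / np.mean(w))
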