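"""Indirect-calorimetry engine for whole-room metabolic chamber sessions.

Converts minute-resolution gas exchange (VO2, VCO2 in L/min) plus a 24-hour
urinary nitrogen measurement into the standard chamber phenotypes:

* 24-hour energy expenditure (EE, kcal/day) via the Lusk caloric equivalent
  of oxygen,
* 24-hour respiratory quotient (RQ = VCO2/VO2),
* nitrogen-corrected nonprotein RQ,
* 24-hour protein, carbohydrate and lipid oxidation rates (PROTOX, CARBOX,
  LIPOX) from Frayn-form stoichiometry.

Stoichiometric constants (litres of gas per gram of substrate oxidised and
energy densities) are module-level so the forward direction (synthesising a
gas-exchange day from a known fuel mix) and the inverse direction (solving
for the fuel mix from measured gas exchange) share one source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GasExchangeTrace",
    "UrineNitrogen",
    "CalorimetrySummary",
    "per_minute_rq",
    "per_minute_ee",
    "clean_trace",
    "aggregate_24h",
    "protein_oxidation",
    "nonprotein_rq",
    "substrate_oxidation",
    "energy_closure",
    "summarize_session",
    "gas_from_substrates",
]

# Lusk equation: EE [kcal/min] = VO2 [L/min] * (4.686 + (RQ - 0.707) * 0.361/0.293).
# 4.686 kcal/L O2 is the caloric equivalent of oxygen at the fat-oxidation
# baseline RQ of 0.707; the slope term interpolates toward 5.047 at RQ = 1.
LUSK_BASE_KCAL_PER_L_O2 = 4.686
LUSK_BASE_RQ = 0.707
LUSK_SLOPE = 0.361 / 0.293

# Litres of O2 consumed / CO2 produced per gram of substrate oxidised.
O2_L_PER_G = {"carb": 0.746, "fat": 2.019, "protein": 0.966}
CO2_L_PER_G = {"carb": 0.746, "fat": 1.427, "protein": 0.782}

# Metabolisable energy densities, kcal per gram oxidised.
KCAL_PER_G = {"carb": 3.74, "fat": 9.46, "protein": 4.70}

# Grams of protein represented by one gram of urinary nitrogen.
PROTEIN_G_PER_G_N = 6.25

# Frayn-form inversion coefficients (gas totals in L/day, nitrogen in g/day).
_FRAYN_CARB = (4.55, 3.21, 2.87)   # carb_g = a*VCO2 - b*VO2 - c*N
_FRAYN_LIP = (1.67, 1.92)          # lipox_g = a*(VO2 - VCO2) - b*N

# Physiologic plausibility band for the nonprotein RQ; values outside are
# flagged (sensor drift, incomplete urine collection) but never discarded.
NPRQ_BAND = (0.69, 1.05)

MINUTES_PER_DAY = 1440


class InvalidMinuteError(ValueError):
    """A per-minute gas value is nonphysiologic (VO2 <= 0)."""


class TraceCoverageError(ValueError):
    """A session's minute coverage is too sparse to summarise."""


@dataclass
class GasExchangeTrace:
    """Per-minute VO2/VCO2 series for one chamber session.

    ``minute`` indexes from 0 (chamber entry) to at most 1439; ``vo2`` and
    ``vco2`` are in L/min. ``activity_pct`` (radar % time in motion) is
    optional and carried through untouched.
    """

    participant_id: str
    chamber_id: str
    minute: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    activity_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.minute = np.asarray(self.minute, dtype=int)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if len(self.minute) != len(self.vo2) or len(self.vo2) != len(self.vco2):
            raise ValueError("minute, vo2 and vco2 must have equal length")
        if len(self.minute) > MINUTES_PER_DAY:
            raise ValueError("a session holds at most 1440 minutes")
        if len(np.unique(self.minute)) != len(self.minute):
            raise ValueError("minute indices must be unique")
        if np.any((self.minute < 0) | (self.minute >= MINUTES_PER_DAY)):
            raise ValueError("minute indices must lie in [0, 1439]")

    def __len__(self) -> int:
        return len(self.minute)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "chamber_id": self.chamber_id,
                "minute": self.minute,
                "vo2_l_min": self.vo2,
                "vco2_l_min": self.vco2,
            }
        )
        if self.activity_pct is not None:
            df["activity_pct"] = self.activity_pct
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GasExchangeTrace":
        """Build a trace from one session's rows of the standard CSV dialect
        (columns participant_id, chamber_id, minute, vo2_l_min, vco2_l_min)."""
        pid = df["participant_id"].iloc[0]
        cid = df["chamber_id"].iloc[0]
        if df["participant_id"].nunique() > 1 or df["chamber_id"].nunique() > 1:
            raise ValueError("frame mixes sessions; filter to one (participant, chamber)")
        act = df["activity_pct"].to_numpy() if "activity_pct" in df.columns else None
        return cls(
            participant_id=str(pid),
            chamber_id=str(cid),
            minute=df["minute"].to_numpy(),
            vo2=df["vo2_l_min"].to_numpy(),
            vco2=df["vco2_l_min"].to_numpy(),
            activity_pct=act,
        )


@dataclass
class UrineNitrogen:
    """24-hour urinary nitrogen excretion for one chamber session (g/day)."""

    chamber_id: str
    nitrogen_g_per_day: float

    def __post_init__(self) -> None:
        if self.nitrogen_g_per_day < 0:
            raise ValueError("urinary nitrogen must be nonnegative")


@dataclass
class CalorimetrySummary:
    """24-hour phenotypes for one chamber session.

    Oxidation rates are reported both in g/day and kcal/day. ``closure_error``
    is the relative mismatch between Lusk EE and substrate-accounted energy;
    it is recorded, never used to reject a session. ``flags`` collects
    quality annotations (out-of-band npRQ, negative oxidation estimates).
    """

    participant_id: str
    chamber_id: str
    ee24: float
    rq24: float
    nprq: float
    protox_g: float
    carbox_g: float
    lipox_g: float
    protox: float
    carbox: float
    lipox: float
    closure_error: float
    vo2_24h: float
    vco2_24h: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "participant_id", "chamber_id", "ee24", "rq24", "nprq",
            "protox_g", "carbox_g", "lipox_g", "protox", "carbox", "lipox",
            "closure_error", "vo2_24h", "vco2_24h")}
        d["flags"] = ";".join(self.flags)
        return d


def per_minute_rq(vo2, vco2):
    """Respiratory quotient VCO2/VO2 for one minute (scalar or array)."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 <= 0):
        raise InvalidMinuteError("VO2 must be positive to form an RQ")
    out = vco2 / vo2
    return float(out) if out.ndim == 0 else out


def per_minute_ee(vo2, rq):
    """Energy expenditure (kcal/min) from the Lusk caloric equivalent of O2.

    EE = VO2 * (4.686 + (RQ - 0.707) * 0.361/0.293); the bracket is the
    kcal-per-litre-O2 factor at the measured RQ.
    """
    vo2 = np.asarray(vo2, dtype=float)
    rq = np.asarray(rq, dtype=float)
    if np.any(vo2 <= 0):
        raise InvalidMinuteError("VO2 must be positive")
    out = vo2 * (LUSK_BASE_KCAL_PER_L_O2 + (rq - LUSK_BASE_RQ) * LUSK_SLOPE)
    return float(out) if out.ndim == 0 else out


def clean_trace(trace: GasExchangeTrace, *, max_gap: int = 5,
                min_coverage: float = 0.95) -> GasExchangeTrace:
    """Apply the minute-gap policy: interpolate short gaps, reject sparse traces.

    Missing minutes (absent indices or non-finite/nonpositive VO2) are filled
    by linear interpolation when each gap spans at most ``max_gap`` consecutive
    minutes. Sessions with a longer gap, or with observed coverage below
    ``min_coverage`` of 1440 minutes, raise :class:`TraceCoverageError`.
    Leading/trailing gaps are extended from the nearest observed value.
    """
    full = np.arange(MINUTES_PER_DAY)
    vo2 = np.full(MINUTES_PER_DAY, np.nan)
    vco2 = np.full(MINUTES_PER_DAY, np.nan)
    vo2[trace.minute] = trace.vo2
    vco2[trace.minute] = trace.vco2
    bad = ~np.isfinite(vo2) | ~np.isfinite(vco2) | (vo2 <= 0) | (vco2 < 0)
    vo2[bad] = np.nan
    vco2[bad] = np.nan

    observed = np.isfinite(vo2)
    if observed.mean() < min_coverage:
        raise TraceCoverageError(
            f"session {trace.chamber_id}: only {observed.mean():.1%} of minutes observed "
            f"(< {min_coverage:.0%})"
        )
    # longest run of consecutive missing minutes
    miss = ~observed
    if miss.any():
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, miss.view(np.int8), 0])))[::2]
        if runs.max() > max_gap:
            raise TraceCoverageError(
                f"session {trace.chamber_id}: gap of {runs.max()} min exceeds {max_gap}"
            )
        obs_idx = np.flatnonzero(observed)
        vo2 = np.interp(full, obs_idx, vo2[obs_idx])
        vco2 = np.interp(full, obs_idx, vco2[obs_idx])

    return GasExchangeTrace(
        participant_id=trace.participant_id,
        chamber_id=trace.chamber_id,
        minute=full,
        vo2=vo2,
        vco2=vco2,
    )


def aggregate_24h(trace: GasExchangeTrace) -> tuple[float, float]:
    """24-hour EE (kcal/day) and RQ for a cleaned trace.

    EE extrapolates the mean per-minute Lusk EE by 1440; RQ is the ratio of
    total VCO2 to total VO2 over retained minutes (ratio-of-totals, so each
    litre of gas carries equal weight regardless of minute-to-minute EE).
    """
    rq = per_minute_rq(trace.vo2, trace.vco2)
    ee_min = per_minute_ee(trace.vo2, rq)
    ee24 = float(np.mean(ee_min)) * MINUTES_PER_DAY
    rq24 = float(np.sum(trace.vco2) / np.sum(trace.vo2))
    return ee24, rq24


def protein_oxidation(nitrogen: UrineNitrogen | float) -> tuple[float, float]:
    """24-hour protein oxidation (g/day, kcal/day) from urinary nitrogen.

    protox_g = 6.25 x nitrogen; kcal at 4.70 kcal/g protein.
    """
    n = nitrogen.nitrogen_g_per_day if isinstance(nitrogen, UrineNitrogen) else float(nitrogen)
    if n < 0:
        raise ValueError("urinary nitrogen must be nonnegative")
    protox_g = PROTEIN_G_PER_G_N * n
    return protox_g, protox_g * KCAL_PER_G["protein"]


def nonprotein_rq(vo2_24h: float, vco2_24h: float, protox_g: float) -> tuple[float, list[str]]:
    """Nonprotein RQ from 24-h gas totals (L/day) and protein oxidised (g/day).

    Subtracts the gas exchange attributable to protein (0.966 L O2 and
    0.782 L CO2 per gram) before forming the quotient. Values outside the
    plausibility band (0.69, 1.05) are returned with a flag, not dropped.
    """
    o2_prot = O2_L_PER_G["protein"] * protox_g
    co2_prot = CO2_L_PER_G["protein"] * protox_g
    if o2_prot >= vo2_24h:
        raise ValueError("protein-attributed O2 exceeds measured VO2")
    nprq = (vco2_24h - co2_prot) / (vo2_24h - o2_prot)
    flags = []
    if not (NPRQ_BAND[0] < nprq < NPRQ_BAND[1]):
        flags.append("nprq_out_of_band")
    return nprq, flags


def substrate_oxidation(vo2_24h: float, vco2_24h: float,
                        nitrogen_g: float) -> tuple[dict, list[str]]:
    """24-hour substrate oxidation from gas totals (L/day) and urinary N (g/day).

    Frayn-form inversion:

        carbox_g = 4.55*VCO2 - 3.21*VO2 - 2.87*N
        lipox_g  = 1.67*(VO2 - VCO2)    - 1.92*N
        protox_g = 6.25*N

    Negative estimates (possible at extreme RQ, e.g. net lipogenesis) are
    retained with a flag so downstream models can exclude them explicitly.
    Returns a dict with *_g and *_kcal entries plus the flag list.
    """
    protox_g, protox_kcal = protein_oxidation(nitrogen_g)
    a, b, c = _FRAYN_CARB
    carbox_g = a * vco2_24h - b * vo2_24h - c * nitrogen_g
    d, e = _FRAYN_LIP
    lipox_g = d * (vo2_24h - vco2_24h) - e * nitrogen_g
    flags = []
    if carbox_g < 0:
        flags.append("negative_carbox")
    if lipox_g < 0:
        flags.append("negative_lipox")
    out = {
        "protox_g": protox_g,
        "carbox_g": carbox_g,
        "lipox_g": lipox_g,
        "protox_kcal": protox_kcal,
        "carbox_kcal": carbox_g * KCAL_PER_G["carb"],
        "lipox_kcal": lipox_g * KCAL_PER_G["fat"],
    }
    return out, flags


def energy_closure(ee24: float, protox_kcal: float, carbox_kcal: float,
                   lipox_kcal: float) -> float:
    """Relative mismatch between substrate-accounted energy and Lusk EE."""
    if ee24 <= 0:
        raise ValueError("ee24 must be positive")
    return abs(protox_kcal + carbox_kcal + lipox_kcal - ee24) / ee24


def summarize_session(trace: GasExchangeTrace, nitrogen: UrineNitrogen,
                      *, clean: bool = True) -> CalorimetrySummary:
    """Full pipeline for one session: clean, aggregate, nitrogen-correct, invert."""
    if clean:
        trace = clean_trace(trace)
    ee24, rq24 = aggregate_24h(trace)
    vo2_24h = float(np.sum(trace.vo2)) * MINUTES_PER_DAY / len(trace)
    vco2_24h = float(np.sum(trace.vco2)) * MINUTES_PER_DAY / len(trace)
    ox, flags = substrate_oxidation(vo2_24h, vco2_24h, nitrogen.nitrogen_g_per_day)
    nprq, nprq_flags = nonprotein_rq(vo2_24h, vco2_24h, ox["protox_g"])
    closure = energy_closure(ee24, ox["protox_kcal"], ox["carbox_kcal"], ox["lipox_kcal"])
    return CalorimetrySummary(
        participant_id=trace.participant_id,
        chamber_id=trace.chamber_id,
        ee24=ee24,
        rq24=rq24,
        nprq=nprq,
        protox_g=ox["protox_g"],
        carbox_g=ox["carbox_g"],
        lipox_g=ox["lipox_g"],
        protox=ox["protox_kcal"],
        carbox=ox["carbox_kcal"],
        lipox=ox["lipox_kcal"],
        closure_error=closure,
        vo2_24h=vo2_24h,
        vco2_24h=vco2_24h,
        flags=flags + nprq_flags,
    )


def summarize_sessions(traces: pd.DataFrame, nitrogen: pd.DataFrame) -> pd.DataFrame:
    """Summarise every session in a long trace table.

    ``traces`` uses the standard dialect (participant_id, chamber_id, minute,
    vo2_l_min, vco2_l_min); ``nitrogen`` has columns chamber_id,
    nitrogen_g_per_day. Returns one row per session.
    """
    n_by_chamber = nitrogen.set_index("chamber_id")["nitrogen_g_per_day"]
    rows = []
    for (pid, cid), grp in traces.groupby(["participant_id", "chamber_id"], sort=True):
        tr = GasExchangeTrace.from_frame(grp)
        un = UrineNitrogen(chamber_id=str(cid), nitrogen_g_per_day=float(n_by_chamber[cid]))
        rows.append(summarize_session(tr, un).to_dict())
    return pd.DataFrame(rows)


def gas_from_substrates(carb_g: float, fat_g: float, prot_g: float) -> dict:
    """Forward stoichiometry: daily gas totals and energy for a fuel mix.

    Returns VO2/VCO2 in L/day, urinary nitrogen in g/day and metabolisable
    energy in kcal/day for the given grams of each substrate oxidised. This
    is the oracle direction that :func:`substrate_oxidation` inverts.
    """
    if min(carb_g, fat_g, prot_g) < 0:
        raise ValueError("substrate masses must be nonnegative")
    vo2 = carb_g * O2_L_PER_G["carb"] + fat_g * O2_L_PER_G["fat"] + prot_g * O2_L_PER_G["protein"]
    vco2 = carb_g * CO2_L_PER_G["carb"] + fat_g * CO2_L_PER_G["fat"] + prot_g * CO2_L_PER_G["protein"]
    kcal = carb_g * KCAL_PER_G["carb"] + fat_g * KCAL_PER_G["fat"] + prot_g * KCAL_PER_G["protein"]
    return {
        "vo2_l": vo2,
        "vco2_l": vco2,
        "nitrogen_g": prot_g / PROTEIN_G_PER_G_N,
        "kcal": kcal,
    }
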