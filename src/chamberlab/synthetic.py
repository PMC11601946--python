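"""Synthetic cohort generator.

Produces every data stream the analysis consumes — participants, crossover
schedules, minute-level chamber gas exchange, urinary nitrogen, pre/post
metabolite panels, pooled-QC replicates and NEFA — with the statistical
structure the models assume, plus a ``SimTruth`` record of every generating
parameter so recovery can be tested.

The generative model, top to bottom:

* Energy need: allometric in body weight, EB_kcal = 65 * kg^0.75 * lognormal
  jitter. Only relative structure matters downstream.
* Gas exchange: each session oxidises a daily fuel mix (carbohydrate / fat /
  protein energy fractions) pulled toward the diet's composition, with a
  per-session jitter so substrate preference varies between participants
  within a diet. Minute-level VO2/VCO2 follow from forward stoichiometry
  shaped by a diurnal profile (sleep dip, post-meal thermogenesis bumps at
  the 11:00 / 16:00 / 19:00 meal times) plus AR(1) multiplicative noise.
  Fasting shifts the oxidised mix linearly toward fat across the day.
* Urinary nitrogen equals protein oxidised / 6.25.
* Metabolome: prechamber abundances log-normal; postchamber log2 level =
  prechamber + diet-by-class effect + coupling x standardized session lipid
  oxidation + participant random intercept + residual noise. Optional
  missingness, outliers and pooled-QC replicates exercise the QC rules.
* NEFA: postchamber level = prechamber + slope x standardized LIPOX + noise,
  tying circulating fatty acids to realized fat oxidation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calorimetry as cal
from .calorimetry import GasExchangeTrace, UrineNitrogen
from .protocol import (
    ChamberSchedule,
    DietPrescription,
    Participant,
    build_diet_library,
    randomize_schedule,
)

__all__ = [
    "METABOLITE_CLASSES",
    "SimConfig",
    "SimTruth",
    "StudyData",
    "simulate_participants",
    "simulate_trace",
    "simulate_metabolome",
    "simulate_nefa",
    "simulate_study",
]

METABOLITE_CLASSES = (
    "acylcarnitines",
    "amino_acids",
    "glycerophospholipids",
    "fatty_acyls",
    "other",
)

# Diet-by-class mean log2 fold-change effects. Signs encode the fasting /
# carbohydrate axis: acylcarnitines and fatty acyls rise when fat oxidation
# dominates (FAST, FNP, HPF) and fall under carbohydrate surplus (CNP);
# glycerophospholipids move oppositely; amino acids fall in fasting except
# the branched-chain subset, which rises.
DEFAULT_EFFECT_MATRIX = pd.DataFrame(
    {
        "acylcarnitines":       {"EB": 0.0, "FAST": 0.8, "SOF": 0.0, "LPF": 0.0, "FNP": 0.5, "HPF": 0.4, "CNP": -0.5},
        "amino_acids":          {"EB": 0.0, "FAST": -0.4, "SOF": 0.0, "LPF": -0.3, "FNP": 0.0, "HPF": 0.3, "CNP": 0.0},
        "glycerophospholipids": {"EB": 0.0, "FAST": -0.5, "SOF": 0.1, "LPF": 0.2, "FNP": -0.3, "HPF": -0.3, "CNP": 0.4},
        "fatty_acyls":          {"EB": 0.0, "FAST": 0.6, "SOF": 0.0, "LPF": 0.0, "FNP": 0.4, "HPF": 0.3, "CNP": -0.4},
        "other":                {"EB": 0.0, "FAST": 0.0, "SOF": 0.0, "LPF": 0.0, "FNP": 0.0, "HPF": 0.0, "CNP": 0.0},
    }
)

# log2 change per SD of session lipid oxidation, by class: the within-diet
# physiology coupling that the pooled association models recover.
DEFAULT_LIPOX_COUPLING = {
    "acylcarnitines": 0.30,
    "amino_acids": 0.0,
    "glycerophospholipids": -0.20,
    "fatty_acyls": 0.25,
    "other": 0.0,
}

# Whole-day EE relative to energy need: fasting suppresses EE slightly,
# overfeeding raises it via diet-induced thermogenesis (protein most).
DIET_EE_FACTOR = {
    "EB": 1.00, "FAST": 0.92, "SOF": 1.07, "LPF": 1.05,
    "FNP": 1.06, "HPF": 1.10, "CNP": 1.08,
}

MEAL_MINUTES = (240, 540, 720)  # 11:00, 16:00, 19:00 after 07:00 entry
SLEEP_START_MINUTE = 960        # 23:00
BASELINE_OX_MIX = (0.50, 0.30, 0.20)
FAST_END_MIX = (0.10, 0.80, 0.10)


@dataclass
class SimConfig:
    """All generator knobs with study-condition defaults."""

    n_participants: int = 30
    n_metabolites: int = 80
    seed: int = 0

    # cohort marginals
    frac_female: float = 0.20
    age_mean: float = 38.0
    age_sd: float = 10.0
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    race_levels: tuple = ("groupA", "groupB", "groupC")
    race_probs: tuple = (0.60, 0.25, 0.15)
    n_weight_days: int = 37
    weight_day_cv: float = 0.004  # daily scale noise, fraction of weight

    # gas-exchange traces
    trace_noise_sd: float = 0.03     # AR(1) multiplicative metabolic noise
    trace_ar1: float = 0.90
    measurement_noise_sd: float = 0.01
    mix_jitter_sd: float = 0.05      # per-session fat-fraction jitter (energy frac)
    diet_mix_weight: float = 0.5     # pull of oxidised mix toward diet composition
    sleep_dip: float = 0.80          # sleeping EE relative to daytime
    meal_bump_amp: float = 0.25
    meal_bump_sd_min: float = 45.0

    # metabolome
    class_probs: tuple = (0.20, 0.25, 0.25, 0.15, 0.15)
    bcaa_frac_of_aa: float = 0.20
    effect_matrix: pd.DataFrame | None = None      # diets x classes, log2
    bcaa_fast_effect: float = 0.4                  # overrides amino_acids under FAST
    lipox_coupling: dict | None = None             # class -> log2 per SD LIPOX
    participant_sd: float = 0.15                   # random intercept, log2
    residual_sd: float = 0.25                      # residual, log2
    baseline_log2_range: tuple = (10.0, 20.0)
    baseline_between_sd: float = 0.6
    baseline_within_sd: float = 0.3
    missing_metabolite_frac: float = 0.05
    n_outliers: int = 2
    outlier_z: float = 8.0
    qc_replicate_frac: float = 0.10
    qc_cv_target: float = 0.05

    # NEFA (mEq/L)
    nefa_baseline_mean: float = 0.50
    nefa_baseline_sd: float = 0.10
    nefa_lipox_slope: float = 0.15
    nefa_noise_sd: float = 0.05

    def resolved_effect_matrix(self) -> pd.DataFrame:
        m = self.effect_matrix if self.effect_matrix is not None else DEFAULT_EFFECT_MATRIX
        return m.copy()

    def resolved_coupling(self) -> dict:
        return dict(self.lipox_coupling if self.lipox_coupling is not None
                    else DEFAULT_LIPOX_COUPLING)


@dataclass
class SimTruth:
    """Generating parameters retained for parameter-recovery tests."""

    energy_need: dict = field(default_factory=dict)          # participant -> kcal/day
    session_substrate_g: dict = field(default_factory=dict)  # chamber -> {carb,fat,prot}
    session_lipox_kcal: dict = field(default_factory=dict)
    metabolite_effects: dict = field(default_factory=dict)   # metabolite -> {diet: log2}
    lipox_coupling: dict = field(default_factory=dict)       # metabolite -> log2 per SD
    nefa_slope: float = 0.0
    injected_missing: list = field(default_factory=list)
    injected_outliers: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))


@dataclass
class StudyData:
    """The complete simulated dataset bundle."""

    participants: list
    schedules: list
    traces: pd.DataFrame
    nitrogen: pd.DataFrame
    metabolome: pd.DataFrame
    qc_replicates: pd.DataFrame
    nefa: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": p.id,
                    "age": p.age,
                    "sex": p.sex,
                    "race": p.race,
                    "bmi": p.bmi,
                    "fasting_glucose": p.fasting_glucose,
                    "glucose_2h": p.glucose_2h,
                    "weight_kg": float(np.mean(p.weight_series)),
                }
                for p in self.participants
            ]
        )

    def schedules_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.schedules], ignore_index=True)

    def write(self, outdir: str | Path) -> None:
        """Write the dataset directory in the CSV dialects the analysis reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants_frame().to_csv(out / "participants.csv", index=False)
        self.schedules_frame().to_csv(out / "schedule.csv", index=False)
        self.traces.to_csv(out / "traces.csv", index=False)
        self.nitrogen.to_csv(out / "nitrogen.csv", index=False)
        self.metabolome.to_csv(out / "metabolome.csv", index=False)
        self.qc_replicates.to_csv(out / "qc_replicates.csv", index=False)
        self.nefa.to_csv(out / "nefa.csv", index=False)
        self.truth.to_json(out / "truth.json")


def _energy_need(weight_kg: float, rng: np.random.Generator) -> float:
    """Allometric EB energy need: 65 * kg^0.75, ~8% lognormal between-person."""
    return 65.0 * weight_kg ** 0.75 * float(np.exp(rng.normal(0.0, 0.08)))


def simulate_participants(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw a cohort of eligible participants; deterministic per seed.

    Returns ``(participants, energy_need)`` where ``energy_need`` maps
    participant id to the true EB 24-hour EE (kcal/day).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    participants, need = [], {}
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        sex = "F" if rng.random() < config.frac_female else "M"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 65))
        race = str(rng.choice(config.race_levels, p=config.race_probs))
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 18.5, 45))
        height_m = rng.normal(1.62 if sex == "F" else 1.76, 0.06)
        weight = bmi * height_m ** 2
        series = weight * (1 + rng.normal(0, config.weight_day_cv, config.n_weight_days))
        fasting = float(np.clip(rng.normal(88, 6), 60, 99.9))
        g2h = float(np.clip(rng.normal(110, 15), 60, 139.9))
        p = Participant(
            id=pid, age=age, sex=sex, race=race, bmi=bmi,
            weight_series=list(series), fasting_glucose=fasting, glucose_2h=g2h,
        )
        participants.append(p)
        need[pid] = _energy_need(weight, rng)
    return participants, need


def _minute_energy_weights(diet_name: str, config: SimConfig) -> np.ndarray:
    """Relative per-minute energy expenditure profile (sums to 1)."""
    m = np.arange(cal.MINUTES_PER_DAY, dtype=float)
    w = np.ones(cal.MINUTES_PER_DAY)
    w[m >= SLEEP_START_MINUTE] = config.sleep_dip
    if diet_name != "FAST":
        for meal in MEAL_MINUTES:
            w += config.meal_bump_amp * np.exp(
                -0.5 * ((m - meal - 60.0) / config.meal_bump_sd_min) ** 2
            )
    return w / w.sum()


def _session_mix(diet: DietPrescription, config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-minute oxidised-fuel energy fractions, shape (1440, 3)."""
    n = cal.MINUTES_PER_DAY
    base = np.asarray(BASELINE_OX_MIX)
    if diet.name == "FAST":
        # fed-state mix drains into fat oxidation across the fasting day
        t = np.linspace(0.0, 1.0, n)[:, None]
        mix = (1 - t) * base + t * np.asarray(FAST_END_MIX)
    else:
        w = config.diet_mix_weight
        daily = (1 - w) * base + w * np.asarray(diet.fractions)
        mix = np.tile(daily, (n, 1))
    # per-session substrate-preference jitter: move energy between carb and fat
    # (positive shift = more fat oxidised); clipped to keep both fractions >= 2%
    shift = rng.normal(0.0, config.mix_jitter_sd)
    shift = float(np.clip(shift, 0.02 - mix[:, 1].min(), mix[:, 0].min() - 0.02)) \
        if config.mix_jitter_sd > 0 else 0.0
    mix = mix + np.array([-shift, shift, 0.0])
    return np.clip(mix, 1e-6, None) / np.clip(mix, 1e-6, None).sum(axis=1, keepdims=True)


def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi ** 2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innov[t]
    return out


def simulate_trace(
    participant_id: str,
    diet: DietPrescription,
    energy_need_kcal: float,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    chamber_id: str | None = None,
    mix_override: tuple[float, float, float] | None = None,
    noise: bool = True,
) -> tuple[GasExchangeTrace, UrineNitrogen, dict]:
    """Forward-synthesize one chamber day.

    The day's total EE is the participant's energy need scaled by a
    diet-specific thermogenesis factor; the oxidised fuel mix comes from the
    diet (or ``mix_override`` as carb/fat/protein energy fractions); minute
    gas exchange follows from stoichiometry shaped by the diurnal profile.
    Returns the trace, the consistent urinary nitrogen, and the truth dict
    (substrate grams, total EE, LIPOX kcal).
    """
    cid = chamber_id or f"{participant_id}_{diet.name}"
    ee_total = energy_need_kcal * DIET_EE_FACTOR[diet.name]
    weights = _minute_energy_weights(diet.name, config)
    if mix_override is not None:
        mix = np.tile(np.asarray(mix_override, dtype=float), (cal.MINUTES_PER_DAY, 1))
        mix = mix / mix.sum(axis=1, keepdims=True)
    else:
        mix = _session_mix(diet, config, rng)

    energy_min = ee_total * weights                       # kcal per minute
    grams = energy_min[:, None] * mix / np.array(
        [cal.KCAL_PER_G["carb"], cal.KCAL_PER_G["fat"], cal.KCAL_PER_G["protein"]]
    )
    o2 = np.array([cal.O2_L_PER_G["carb"], cal.O2_L_PER_G["fat"], cal.O2_L_PER_G["protein"]])
    co2 = np.array([cal.CO2_L_PER_G["carb"], cal.CO2_L_PER_G["fat"], cal.CO2_L_PER_G["protein"]])
    vo2 = grams @ o2
    vco2 = grams @ co2

    if noise and config.trace_noise_sd > 0:
        shared = _ar1(cal.MINUTES_PER_DAY, config.trace_noise_sd, config.trace_ar1, rng)
        vo2 = vo2 * (1 + shared) * (1 + rng.normal(0, config.measurement_noise_sd, vo2.size))
        vco2 = vco2 * (1 + shared) * (1 + rng.normal(0, config.measurement_noise_sd, vco2.size))
        vo2 = np.clip(vo2, 1e-4, None)
        vco2 = np.clip(vco2, 0.0, None)

    totals = grams.sum(axis=0)
    truth = {
        "carb_g": float(totals[0]),
        "fat_g": float(totals[1]),
        "prot_g": float(totals[2]),
        "ee_kcal": float(ee_total),
        "lipox_kcal": float(totals[1] * cal.KCAL_PER_G["fat"]),
    }
    trace = GasExchangeTrace(
        participant_id=participant_id, chamber_id=cid,
        minute=np.arange(cal.MINUTES_PER_DAY), vo2=vo2, vco2=vco2,
    )
    nitrogen = UrineNitrogen(chamber_id=cid,
                             nitrogen_g_per_day=float(totals[2] / cal.PROTEIN_G_PER_G_N))
    return trace, nitrogen, truth


def _metabolite_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = rng.choice(METABOLITE_CLASSES, size=config.n_metabolites, p=config.class_probs)
    names = [f"met{i + 1:04d}" for i in range(config.n_metabolites)]
    sub = np.array([""] * config.n_metabolites, dtype=object)
    aa_idx = np.flatnonzero(classes == "amino_acids")
    n_bcaa = int(round(config.bcaa_frac_of_aa * aa_idx.size))
    if n_bcaa:
        sub[rng.choice(aa_idx, size=n_bcaa, replace=False)] = "bcaa"
    return pd.DataFrame({"metabolite": names, "met_class": classes, "subclass": sub})


def simulate_metabolome(
    sessions: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate the pre/post metabolite panel for a session table.

    ``sessions`` needs columns participant_id, chamber_id, diet,
    chamber_order and lipox_kcal (the realized session lipid oxidation the
    coupling acts on). Returns (long panel, pooled-QC replicate table, truth).
    """
    truth = truth or SimTruth()
    mets = _metabolite_table(config, rng)
    effects = config.resolved_effect_matrix()
    coupling = config.resolved_coupling()

    lip = sessions["lipox_kcal"].to_numpy(dtype=float)
    lip_z = (lip - lip.mean()) / lip.std() if lip.std() > 0 else np.zeros_like(lip)

    pids = sessions["participant_id"].to_numpy()
    uniq_pids = pd.unique(pids)
    n_s, n_m = len(sessions), len(mets)

    # per-metabolite diet effect vectors (BCAA override under FAST)
    diet_names = effects.index.to_list()
    eff = np.zeros((len(diet_names), n_m))
    for j, row in enumerate(mets.itertuples()):
        col = effects[row.met_class].to_numpy(dtype=float).copy()
        if row.subclass == "bcaa":
            col[diet_names.index("FAST")] = config.bcaa_fast_effect
        eff[:, j] = col
        truth.metabolite_effects[row.metabolite] = dict(zip(diet_names, col))
        truth.lipox_coupling[row.metabolite] = float(coupling[row.met_class])
    diet_idx = sessions["diet"].map({d: i for i, d in enumerate(diet_names)}).to_numpy()

    mu = rng.uniform(*config.baseline_log2_range, n_m)
    part_baseline = rng.normal(0.0, config.baseline_between_sd, (uniq_pids.size, n_m))
    part_intercept = rng.normal(0.0, config.participant_sd, (uniq_pids.size, n_m))
    pid_idx = pd.Series(np.arange(uniq_pids.size), index=uniq_pids)[pids].to_numpy()

    pre = (mu[None, :] + part_baseline[pid_idx]
           + rng.normal(0.0, config.baseline_within_sd, (n_s, n_m)))
    gamma = np.array([coupling[c] for c in mets["met_class"]])
    post = (pre + eff[diet_idx] + lip_z[:, None] * gamma[None, :]
            + part_intercept[pid_idx]
            + rng.normal(0.0, config.residual_sd, (n_s, n_m)))

    def melt(mat: np.ndarray, timepoint: str) -> pd.DataFrame:
        df = pd.DataFrame(2.0 ** mat, columns=mets["metabolite"])
        df = pd.concat(
            [sessions[["participant_id", "chamber_id", "diet", "chamber_order"]]
             .reset_index(drop=True), df], axis=1)
        long = df.melt(
            id_vars=["participant_id", "chamber_id", "diet", "chamber_order"],
            var_name="metabolite", value_name="abundance")
        long["timepoint"] = timepoint
        return long

    panel = pd.concat([melt(pre, "pre"), melt(post, "post")], ignore_index=True)
    panel = panel.merge(mets, on="metabolite", how="left")

    # injected missingness: a few metabolites carry sporadic missing values
    n_missing = int(round(config.missing_metabolite_frac * n_m))
    if n_missing:
        missing_mets = rng.choice(mets["metabolite"], size=n_missing, replace=False)
        for m in missing_mets:
            rows = panel.index[panel["metabolite"] == m]
            hit = rng.choice(rows, size=int(rng.integers(1, 4)), replace=False)
            panel.loc[hit, "abundance"] = np.nan
        truth.injected_missing = [str(m) for m in missing_mets]

    # injected prechamber outliers within a (diet, metabolite) group. The QC
    # rule scores each value against a group SD computed WITH the candidate
    # included, which caps the achievable z at (g-1)/sqrt(g) for group size g;
    # the injected value is calibrated against that same inclusive score so a
    # nominal outlier_z of 8 lands as far out as the group size permits.
    for _ in range(config.n_outliers):
        m = str(rng.choice(mets["metabolite"]))
        diet = str(rng.choice([d for d in diet_names if d != "EB"]))
        grp = panel.index[(panel["metabolite"] == m) & (panel["diet"] == diet)
                          & (panel["timepoint"] == "pre")
                          & panel["abundance"].notna()]
        if len(grp) < 4:
            continue
        target = rng.choice(grp)
        others = np.log2(panel.loc[grp.drop(target), "abundance"].astype(float)).to_numpy()
        g = others.size + 1
        target_z = min(config.outlier_z, 0.97 * (g - 1) / np.sqrt(g))

        def inclusive_z(c: float) -> float:
            vals = np.append(others, others.mean() + c * others.std(ddof=1))
            return (vals[-1] - vals.mean()) / vals.std(ddof=1)

        lo, hi = target_z, 1e6
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if inclusive_z(mid) < target_z:
                lo = mid
            else:
                hi = mid
        panel.loc[target, "abundance"] = float(
            2.0 ** (others.mean() + hi * others.std(ddof=1)))
        truth.injected_outliers.append(
            {"metabolite": m, "diet": diet, "row": int(target)})

    # pooled-QC replicates: repeated injections of one pooled sample
    pooled = panel.groupby("metabolite")["abundance"].apply(
        lambda x: float(2.0 ** np.log2(x.dropna()).mean()))
    n_qc = max(3, int(round(config.qc_replicate_frac * n_s * 2)))
    qc = pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(1, n_qc + 1), n_m),
            "metabolite": np.tile(pooled.index.to_numpy(), n_qc),
            "abundance": np.tile(pooled.to_numpy(), n_qc)
            * np.exp(rng.normal(0.0, config.qc_cv_target, n_qc * n_m)),
        }
    )
    return panel, qc, truth


def simulate_nefa(sessions: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator,
                  truth: SimTruth | None = None) -> tuple[pd.DataFrame, SimTruth]:
    """Pre/post NEFA (mEq/L) coupled to standardized session lipid oxidation."""
    truth = truth or SimTruth()
    lip = sessions["lipox_kcal"].to_numpy(dtype=float)
    lip_z = (lip - lip.mean()) / lip.std() if lip.std() > 0 else np.zeros_like(lip)
    pre = np.clip(rng.normal(config.nefa_baseline_mean, config.nefa_baseline_sd,
                             len(sessions)), 0.05, None)
    post = np.clip(
        pre + config.nefa_lipox_slope * lip_z
        + rng.normal(0.0, config.nefa_noise_sd, len(sessions)),
        0.01, None)
    truth.nefa_slope = config.nefa_lipox_slope
    out = sessions[["participant_id", "chamber_id", "diet", "chamber_order"]].copy()
    out["nefa_pre"] = pre
    out["nefa_post"] = post
    return out, truth


def simulate_study(config: SimConfig | None = None) -> StudyData:
    """Run the full generator: cohort, schedules, traces, metabolome, NEFA."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    participants, need = simulate_participants(config, rng)
    diets = build_diet_library()
    by_name = {d.name: d for d in diets}

    truth = SimTruth(energy_need={k: float(v) for k, v in need.items()})
    schedules, trace_frames, nitro_rows, session_rows = [], [], [], []
    for p in participants:
        sched = randomize_schedule(
            p, diets, seed=int(rng.integers(0, 2 ** 31 - 1)), eb_ee=need[p.id])
        schedules.append(sched)
        for sess in sched.chambers:
            diet = by_name[sess.diet]
            cid = f"{p.id}_C{sess.chamber_order}_{sess.diet}"
            trace, nitro, t = simulate_trace(
                p.id, diet, need[p.id], config, rng, chamber_id=cid)
            trace_frames.append(trace.to_frame())
            nitro_rows.append({"participant_id": p.id, "chamber_id": cid,
                               "nitrogen_g_per_day": nitro.nitrogen_g_per_day})
            truth.session_substrate_g[cid] = {
                "carb_g": t["carb_g"], "fat_g": t["fat_g"], "prot_g": t["prot_g"],
                "ee_kcal": t["ee_kcal"]}
            truth.session_lipox_kcal[cid] = t["lipox_kcal"]
            session_rows.append({
                "participant_id": p.id, "chamber_id": cid, "diet": sess.diet,
                "chamber_order": sess.chamber_order, "lipox_kcal": t["lipox_kcal"]})

    sessions = pd.DataFrame(session_rows)
    panel, qc, truth = simulate_metabolome(sessions, config, rng, truth=truth)
    nefa, truth = simulate_nefa(sessions, config, rng, truth=truth)
    return StudyData(
        participants=participants,
        schedules=schedules,
        traces=pd.concat(trace_frames, ignore_index=True),
        nitrogen=pd.DataFrame(nitro_rows),
        metabolome=panel,
        qc_replicates=qc,
        nefa=nefa,
        truth=truth,
        config=config,
    )
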