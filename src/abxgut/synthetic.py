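"""Synthetic register + covariate + microbiome generator with known truth.

Emulates the structure the downstream pipeline assumes: three population
cohorts (a large middle-aged cohort, an older cohort, and a younger
family-structured cohort), per-class monthly antibiotic prescription
histories over 96 months drawn from a prescription register model,
confounding (comorbidity raises both the prescription rate and shifts the
microbiome), plate batch effects, and planted antibiotic effects on
diversity and on species log-abundance that decay exponentially with time
since exposure. Species counts follow a log-normal-Poisson model, giving
overdispersion and realistic zero inflation.

Every generator is bit-reproducible under a fixed seed, and the planted
effects are returned as a :class:`GroundTruth` so recovery can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd

from .exposure import (
    ANTIBIOTIC_CLASSES,
    DAYS_PER_MONTH,
    N_MONTHS,
    classify_atc_series,
)

#: Representative dispensed product per class (code, tablet strength in mg).
CLASS_ATC: dict[str, tuple[str, float | None]] = {
    "tetracyclines": ("J01AA02", 100.0),   # doxycycline 100 mg
    "penicillins_ext": ("J01CA08", None),
    "penicillin_v": ("J01CE02", None),
    "flucloxacillin": ("J01CF05", None),
    "amox_clav": ("J01CR02", None),
    "cephalosporins": ("J01DB05", None),
    "smz_tmp": ("J01EE01", None),
    "macrolides": ("J01FA09", None),
    "clindamycin": ("J01FF01", None),
    "fluoroquinolones": ("J01MA02", None),
    "nitrofurantoin": ("J01XE01", None),
}

#: Default per-class monthly prescription probabilities, chosen so that the
#: implied one-year user proportions approximate the register tabulation of
#: the three Swedish cohorts (e.g. ~6.6%/year for penicillin V).
DEFAULT_CLASS_RATES: dict[str, float] = {
    "penicillin_v": 0.00568,
    "tetracyclines": 0.00288,
    "penicillins_ext": 0.00297,
    "flucloxacillin": 0.00168,
    "fluoroquinolones": 0.00134,
    "nitrofurantoin": 0.00134,
    "clindamycin": 0.00101,
    "smz_tmp": 0.00038,
    "cephalosporins": 0.00042,
    "macrolides": 0.00042,
    "amox_clav": 0.00033,
}

#: Default planted decrements of species richness per course at lag 0,
#: mirroring the strongest published register-linked estimates (clindamycin
#: ~47 fewer species per recent course; fluoroquinolones ~20;
#: flucloxacillin ~21). Classes not listed have no diversity effect.
DEFAULT_DIVERSITY_EFFECT: dict[str, float] = {
    "clindamycin": 47.0,
    "fluoroquinolones": 20.0,
    "flucloxacillin": 21.0,
}

#: Marginal targets for the categorical covariates (gen_participants aims
#: within 10% at n >= 1000).
COVARIATE_TARGETS: dict[str, object] = {
    "female": 0.50,
    "education": {"compulsory": 0.12, "secondary": 0.44, "university": 0.44},
    "smoking": {"never": 0.55, "former": 0.33, "current": 0.12},
    "scandinavian_born": 0.90,
    "charlson2": 0.08,
    "polypharmacy": 0.07,
    "ppi": 0.10,
    "metformin": 0.04,
    "ssri": 0.06,
    "statin": 0.15,
    "beta_blocker": 0.12,
    "antipsychotic": 0.008,
    "ibd": 0.01,
    "pulmonary": 0.02,
}

COHORTS = ("cohort1", "cohort2", "cohort3")  # cohort3 is family-structured


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    diversity_effect is the planted decrement in species richness per course
    at lag 0 (species-count units); species_effects maps class -> species
    index -> log-abundance shift per course at lag 0. Both decay as
    2^(-lag_months / decay_halflife_months). confounding_strength couples the
    comorbidity flag to the prescription rate (multiplier 1 + strength) and
    to the microbiome (a fixed species shift and a small diversity
    decrement). family_sd and plate_sd are per-species log-abundance SDs of
    the family (cohort3 only) and plate random effects.
    """

    n_per_cohort: tuple[int, int, int] = (8488, 4784, 1707)
    months_history: int = N_MONTHS
    class_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_RATES)
    )
    diversity_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERSITY_EFFECT)
    )
    decay_halflife_months: float = 24.0
    species_count: int = 300
    species_effects: dict[str, dict[int, float]] | None = None
    #: optional class -> (female_scale, male_scale) multiplier on the
    #: diversity effect, for planting sex-specific effects; None = no
    #: sex difference
    sex_specific_scale: dict[str, tuple[float, float]] | None = None
    sequencing_depth: int = 30_000
    confounding_strength: float = 0.5
    family_sd: float = 0.3
    plate_sd: float = 0.15
    age_ranges: tuple[tuple[int, int], ...] = ((50, 65), (70, 76), (20, 65))
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_cohort):
            raise ValueError("cohort sizes must be positive")
        if self.decay_halflife_months <= 0:
            raise ValueError("decay_halflife_months must be positive")
        for cls, r in self.class_rates.items():
            if cls not in ANTIBIOTIC_CLASSES:
                raise ValueError(f"unknown antibiotic class in class_rates: {cls!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {cls} not in [0, 1]: {r}")
        for cls in self.diversity_effect:
            if cls not in ANTIBIOTIC_CLASSES:
                raise ValueError(f"unknown class in diversity_effect: {cls!r}")


@dataclass
class GroundTruth:
    """Planted effects and their decay."""

    diversity_effect: dict[str, float]
    species_effects: dict[str, dict[int, float]]
    decay_halflife_months: float

    def decay(self, lag_months) -> np.ndarray:
        lag = np.asarray(lag_months, dtype=float)
        if math.isinf(self.decay_halflife_months):
            return np.ones_like(lag)
        return 0.5 ** (lag / self.decay_halflife_months)

    def diversity_profile(self, abx_class: str, months=None) -> np.ndarray:
        """Expected richness decrement for one course at each monthly lag."""
        months = np.arange(1, N_MONTHS + 1) if months is None else np.asarray(months)
        e0 = self.diversity_effect.get(abx_class, 0.0)
        return e0 * self.decay(months - 0.5)

    def table(self) -> pd.DataFrame:
        rows = [
            ("diversity", cls, -1, eff, self.decay_halflife_months)
            for cls, eff in self.diversity_effect.items()
        ]
        for cls, m in self.species_effects.items():
            rows += [
                ("species", cls, sp, eff, self.decay_halflife_months)
                for sp, eff in m.items()
            ]
        return pd.DataFrame(
            rows, columns=["kind", "abx_class", "species", "effect_lag0", "halflife"]
        )


def default_species_effects(species_count: int) -> dict[str, dict[int, float]]:
    """Planted per-species log-abundance shifts for the three classes with
    the most published species associations. Each affected block covers
    ~22%/15%/13% of species; two thirds are depleted, one third enriched."""
    fractions = {"clindamycin": 0.22, "flucloxacillin": 0.15, "fluoroquinolones": 0.13}
    starts = {"clindamycin": 0, "flucloxacillin": species_count // 3,
              "fluoroquinolones": 2 * species_count // 3}
    out: dict[str, dict[int, float]] = {}
    for cls, frac in fractions.items():
        n_aff = max(1, round(frac * species_count))
        idx = [(starts[cls] + i) % species_count for i in range(n_aff)]
        out[cls] = {j: (-0.6 if k % 3 else 0.3) for k, j in enumerate(idx)}
    return out


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------


def gen_participants(config: SimConfig) -> pd.DataFrame:
    """Participant table for the three cohorts, indexed by participant id."""
    rng = np.random.default_rng([config.seed, 11])
    frames = []
    t = COVARIATE_TARGETS
    for k, (cohort, n) in enumerate(zip(COHORTS, config.n_per_cohort)):
        ids = [f"{cohort}_{i:05d}" for i in range(n)]
        lo, hi = config.age_ranges[k]
        age = rng.uniform(lo, hi, n).round(1)
        sex = np.where(rng.random(n) < t["female"], "female", "male")
        edu = rng.choice(
            list(t["education"]), size=n, p=list(t["education"].values())
        )
        smoke = rng.choice(list(t["smoking"]), size=n, p=list(t["smoking"].values()))
        born = np.where(rng.random(n) < t["scandinavian_born"], "scandinavia", "other")
        bmi = np.clip(rng.normal(26.5, 4.0, n), 16, 45).round(1)
        flags = {
            c: (rng.random(n) < t[c]).astype(int)
            for c in ("charlson2", "polypharmacy", "ppi", "metformin", "ssri",
                      "statin", "beta_blocker", "antipsychotic", "ibd", "pulmonary")
        }
        # sampling dates: mostly 2014-2018, a small tail before the 8-year
        # register-coverage cutoff to exercise the incomplete-history rule
        start = pd.Timestamp("2014-01-01")
        offsets = rng.integers(0, 5 * 365, n)
        visit2 = start + pd.to_timedelta(offsets, unit="D")
        early = rng.random(n) < 0.005
        visit2 = visit2.where(
            ~early, pd.Timestamp("2013-02-01") + pd.to_timedelta(offsets % 120, unit="D")
        )
        interval = 1 + rng.poisson(8, n)
        long_gap = rng.random(n) < 0.01
        interval = np.where(long_gap, rng.integers(61, 90, n), interval)
        visit1 = visit2 - pd.to_timedelta(interval, unit="D")
        if cohort == "cohort3":
            sizes = rng.choice([1, 2, 3, 4], size=n, p=[0.4, 0.3, 0.2, 0.1])
            fam, total = [], 0
            fid = 0
            while total < n:
                s = int(sizes[fid % n])
                fam += [f"{cohort}_fam{fid:04d}"] * s
                total += s
                fid += 1
            family = np.array(fam[:n])
        else:
            family = np.array([""] * n)
        frames.append(
            pd.DataFrame(
                {
                    "cohort": cohort, "age": age, "sex": sex, "education": edu,
                    "smoking": smoke, "birth_country": born, "bmi": bmi,
                    "plate": [f"{cohort}_P{i // 96 + 1:02d}" for i in range(n)],
                    "family_id": family,
                    "visit1_date": visit1.normalize(),
                    "visit2_date": visit2.normalize(),
                    "sampling_date": visit2.normalize(),
                    **flags,
                },
                index=pd.Index(ids, name="participant_id"),
            )
        )
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# Prescriptions
# ---------------------------------------------------------------------------


def gen_prescriptions(
    participants: pd.DataFrame, config: SimConfig, post_months: int = 12
) -> pd.DataFrame:
    """Dispensed-prescription register for all participants.

    Per participant, per month in the look-back (and ``post_months`` months
    after sampling, for the negative-control exposure), per class: a
    Bernoulli dispense with probability rate x comorbidity multiplier
    (1 + confounding_strength for comorbid participants). Each record
    carries a valid J01 ATC code for its class, a dispense date inside its
    month window, and a DDD amount.
    """
    rng = np.random.default_rng([config.seed, 23])
    n = len(participants)
    charlson = participants["charlson2"].to_numpy()
    mult = 1.0 + config.confounding_strength * charlson
    sampling = pd.to_datetime(participants["sampling_date"])
    months = np.arange(-post_months, config.months_history)  # negative = post-sampling
    # integer day bounds of month m (1-based pre-sampling): [lo_m, hi_m]
    lo = np.ceil(DAYS_PER_MONTH * months).astype(int)
    hi = np.ceil(DAYS_PER_MONTH * (months + 1)).astype(int) - 1

    frames = []
    for cls, rate in config.class_rates.items():
        p = np.minimum(1.0, rate * mult)
        events = rng.random((n, len(months))) < p[:, None]
        rows, cols = np.nonzero(events)
        if len(rows) == 0:
            continue
        day = rng.integers(lo[cols], hi[cols] + 1)
        dates = sampling.iloc[rows].to_numpy() - day.astype("timedelta64[D]")
        code, strength = CLASS_ATC[cls]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participants.index.to_numpy()[rows],
                    "atc_code": code,
                    "dispense_date": dates,
                    "ddd_total": np.round(rng.uniform(5, 15, len(rows)), 1),
                    "strength_mg": strength if strength is not None else np.nan,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "atc_code", "dispense_date", "ddd_total",
                     "strength_mg"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "dispense_date"], ignore_index=True)


# ---------------------------------------------------------------------------
# Species counts
# ---------------------------------------------------------------------------


def _exposure_decay_weights(
    participants: pd.DataFrame, records: pd.DataFrame, halflife: float
) -> pd.DataFrame:
    """W[i, c] = sum over pre-sampling courses of class c of
    2^(-lag_months / halflife)."""
    W = pd.DataFrame(
        0.0, index=participants.index, columns=list(ANTIBIOTIC_CLASSES)
    )
    if len(records) == 0:
        return W
    rec = records.copy()
    rec["abx_class"] = classify_atc_series(rec["atc_code"])
    rec = rec[rec["abx_class"].isin(ANTIBIOTIC_CLASSES)]
    rec = rec.merge(
        participants[["sampling_date"]], left_on="participant_id", right_index=True
    )
    days = (
        pd.to_datetime(rec["sampling_date"]) - pd.to_datetime(rec["dispense_date"])
    ).dt.days.astype(float)
    rec = rec[(days >= 0) & (days < DAYS_PER_MONTH * N_MONTHS)]
    lag_months = days.loc[rec.index] / DAYS_PER_MONTH
    decay = (
        np.ones(len(rec))
        if math.isinf(halflife)
        else 0.5 ** (lag_months.to_numpy() / halflife)
    )
    agg = (
        pd.DataFrame(
            {"participant_id": rec["participant_id"].to_numpy(),
             "abx_class": rec["abx_class"].to_numpy(), "w": decay}
        )
        .groupby(["participant_id", "abx_class"], observed=True)["w"]
        .sum()
        .unstack(fill_value=0.0)
    )
    W.loc[agg.index, agg.columns] = agg
    return W


def gen_species_counts(
    participants: pd.DataFrame,
    records: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Species count matrix with planted effects, plus the ground truth.

    Counts follow a log-normal-Poisson model: per-species baseline
    log-abundance plus plate, family and comorbidity effects plus the
    planted per-course species shifts (decayed by time since dispense),
    composition-normalized and scaled to the sequencing depth. The richness
    decrement is implemented by stochastically zeroing present species with
    probability D_i / richness_i, where D_i sums the decayed per-course
    diversity effects (plus a small comorbidity term), so the expected
    number of zeroed species equals D_i.
    """
    rng = np.random.default_rng([config.seed, 37])
    S = config.species_count
    n = len(participants)
    effects = (
        config.species_effects
        if config.species_effects is not None
        else default_species_effects(S)
    )
    for cls, m in effects.items():
        if cls not in ANTIBIOTIC_CLASSES:
            raise ValueError(f"species_effects references unknown class {cls!r}")
        bad = [j for j in m if not 0 <= j < S]
        if bad:
            raise ValueError(f"species_effects references unknown species {bad}")

    truth = GroundTruth(
        diversity_effect=dict(config.diversity_effect),
        species_effects={c: dict(m) for c, m in effects.items()},
        decay_halflife_months=config.decay_halflife_months,
    )

    baseline = rng.normal(0.0, 1.2, S)
    plates = participants["plate"].to_numpy()
    plate_levels = pd.unique(plates)
    plate_eff = {
        p: rng.normal(0.0, config.plate_sd, S) for p in plate_levels
    }
    fams = participants["family_id"].to_numpy()
    fam_levels = [f for f in pd.unique(fams) if f]
    fam_eff = {f: rng.normal(0.0, config.family_sd, S) for f in fam_levels}
    comorb_shift = rng.normal(0.0, 1.0, S) * 0.1 * config.confounding_strength

    W = _exposure_decay_weights(participants, records, config.decay_halflife_months)

    shift_mat = np.zeros((len(ANTIBIOTIC_CLASSES), S))
    cls_pos = {c: i for i, c in enumerate(ANTIBIOTIC_CLASSES)}
    for cls, m in effects.items():
        for j, e in m.items():
            shift_mat[cls_pos[cls], j] = e

    log_x = np.tile(baseline, (n, 1))
    log_x += np.array([plate_eff[p] for p in plates])
    fam_rows = np.array(
        [fam_eff[f] if f else np.zeros(S) for f in fams]
    )
    log_x += fam_rows
    log_x += participants["charlson2"].to_numpy()[:, None] * comorb_shift[None, :]
    log_x += W.to_numpy() @ shift_mat

    log_x -= log_x.max(axis=1, keepdims=True)
    x = np.exp(log_x)
    p = x / x.sum(axis=1, keepdims=True)
    counts = rng.poisson(config.sequencing_depth * p)

    # richness decrement by stochastic zeroing of present species
    eff_vec = np.array(
        [config.diversity_effect.get(c, 0.0) for c in ANTIBIOTIC_CLASSES]
    )
    if config.sex_specific_scale:
        female = (participants["sex"].to_numpy() == "female").astype(float)
        scale = np.ones((n, len(ANTIBIOTIC_CLASSES)))
        for cls, (fs, ms) in config.sex_specific_scale.items():
            j = cls_pos[cls]
            scale[:, j] = np.where(female > 0, fs, ms)
        D = (W.to_numpy() * scale) @ eff_vec
    else:
        D = W.to_numpy() @ eff_vec
    D = D + 5.0 * config.confounding_strength * participants["charlson2"].to_numpy()
    present = counts > 0
    n_present = present.sum(axis=1)
    p_drop = np.divide(
        D, n_present, out=np.zeros_like(D, dtype=float), where=n_present > 0
    )
    p_drop = np.clip(p_drop, 0.0, 1.0)
    drop = present & (rng.random((n, S)) < p_drop[:, None])
    counts[drop] = 0
    # a sample is never emptied entirely: the most abundant species survives
    wiped = counts.sum(axis=1) == 0
    if wiped.any():
        top = np.argmax(np.where(present[wiped], 1.0, 0.0) * x[wiped], axis=1)
        counts[np.flatnonzero(wiped), top] = np.maximum(
            1, (config.sequencing_depth * p[wiped, top]).astype(int)
        )

    out = pd.DataFrame(
        counts,
        index=participants.index,
        columns=[f"sp{j:04d}" for j in range(S)],
    )
    return out, truth


@dataclass
class SimData:
    """One synthetic study: linked register, covariates, counts, truth."""

    config: SimConfig
    participants: pd.DataFrame
    records: pd.DataFrame
    counts: pd.DataFrame
    truth: GroundTruth

    def cohort_counts(self, cohort: str) -> pd.DataFrame:
        ids = self.participants.index[self.participants["cohort"] == cohort]
        return self.counts.loc[ids]


def simulate(config: SimConfig | None = None) -> SimData:
    """Generate a full linked synthetic study."""
    config = config or SimConfig()
    participants = gen_participants(config)
    records = gen_prescriptions(participants, config)
    counts, truth = gen_species_counts(participants, records, config)
    return SimData(
        config=config, participants=participants, records=records,
        counts=counts, truth=truth,
    )


def write_dataset(data: SimData, outdir) -> None:
    """Write the tab-delimited pipeline inputs plus ground truth and config."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.participants.to_csv(out / "participants.tsv", sep="\t")
    data.records.to_csv(out / "register.tsv", sep="\t", index=False)
    for cohort in COHORTS:
        data.cohort_counts(cohort).to_csv(out / f"counts_{cohort}.tsv", sep="\t")
    data.truth.table().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    cfg = asdict(data.config)
    cfg["n_per_cohort"] = list(cfg["n_per_cohort"])
    cfg["age_ranges"] = [list(a) for a in cfg["age_ranges"]]
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
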