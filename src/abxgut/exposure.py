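"""Prescription-register antibiotic exposure.

Turns raw dispensed-prescription records (ATC code, date, DDD amount) into the
exposure variables used by the association models: per-class course counts in
three look-back periods (<1 year, 1-4 years, 4-8 years before fecal sampling),
a per-class 96-month binary exposure history, a post-sampling negative-control
exposure, and the eligibility rules (washout, long-term-user DDD rules,
diagnosis-based exclusions, visit-date consistency, register coverage).

Time windows are day-based and half-open, with one year = 365.25 days and one
month = 365.25/12 = 30.4375 days, so every record falls in exactly one period
and one month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger("abxgut")

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375
N_MONTHS = 96
LOOKBACK_DAYS = DAYS_PER_MONTH * N_MONTHS  # 2922.0

#: ATC prefix -> antibiotic class, longest-prefix matched. J01 codes matching
#: none of these map to OTHER_J01 and are excluded from the 11 predictors.
ATC_CLASS_PREFIXES: dict[str, str] = {
    "J01A": "tetracyclines",
    "J01CA": "penicillins_ext",       # extended-spectrum penicillins
    "J01CE": "penicillin_v",          # beta-lactamase-sensitive penicillins
    "J01CF": "flucloxacillin",        # beta-lactamase-resistant penicillins
    "J01CR": "amox_clav",             # penicillins + beta-lactamase inhibitors
    "J01DB": "cephalosporins",
    "J01DC": "cephalosporins",
    "J01DD": "cephalosporins",
    "J01E": "smz_tmp",                # sulfonamides and trimethoprim
    "J01FA": "macrolides",
    "J01FF": "clindamycin",           # lincosamides
    "J01MA": "fluoroquinolones",
    "J01XE01": "nitrofurantoin",
}

#: Canonical order of the 11 antibiotic classes.
ANTIBIOTIC_CLASSES: tuple[str, ...] = (
    "tetracyclines",
    "penicillins_ext",
    "penicillin_v",
    "flucloxacillin",
    "amox_clav",
    "cephalosporins",
    "smz_tmp",
    "macrolides",
    "clindamycin",
    "fluoroquinolones",
    "nitrofurantoin",
)

OTHER_J01 = "other_J01"
NON_ANTIBIOTIC = "non_antibiotic"

#: Period label -> [lower, upper) bound in days before sampling.
PERIOD_BOUNDS: dict[str, tuple[float, float]] = {
    "lt1y": (0.0, 365.25),
    "1to4y": (365.25, 1461.0),
    "4to8y": (1461.0, 2922.0),
}
PERIOD_ORDER: tuple[str, ...] = ("lt1y", "1to4y", "4to8y")

# Specific substances used by the long-term-user rules.
ATC_METHENAMINE = "J01XX05"
ATC_NITROFURANTOIN = "J01XE01"
ATC_TRIMETHOPRIM = "J01EA"
ATC_DOXYCYCLINE = "J01AA02"
ATC_TETRACYCLINE = "J01AA07"
ATC_LYMECYCLINE = "J01AA04"

REGISTER_START = date(2005, 7, 1)

_PREFIXES_BY_LENGTH = sorted(ATC_CLASS_PREFIXES, key=len, reverse=True)


def exposure_column(abx_class: str, period: str) -> str:
    """Name of the course-count column for one class in one period."""
    return f"{abx_class}_{period}"


EXPOSURE_COLUMNS: tuple[str, ...] = tuple(
    exposure_column(c, p) for c in ANTIBIOTIC_CLASSES for p in PERIOD_ORDER
)


def classify_atc(atc_code: str) -> str:
    """Map an ATC code to one of the 11 antibiotic classes.

    Longest-prefix match against the class prefixes. J01 codes that match no
    class prefix return ``OTHER_J01``; non-J01 codes return
    ``NON_ANTIBIOTIC``. Total function: never raises.
    """
    code = str(atc_code).strip().upper()
    for prefix in _PREFIXES_BY_LENGTH:
        if code.startswith(prefix):
            return ATC_CLASS_PREFIXES[prefix]
    if code.startswith("J01"):
        return OTHER_J01
    return NON_ANTIBIOTIC


def classify_atc_series(codes: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_atc` (caches unique codes)."""
    uniq = codes.astype(str).unique()
    mapping = {c: classify_atc(c) for c in uniq}
    return codes.astype(str).map(mapping)


def _dedupe(records: pd.DataFrame) -> pd.DataFrame:
    """One prescription row = one course; duplicate (id, ATC, date) rows are
    register artifacts (e.g. split pharmacy lines) and are dropped."""
    return records.drop_duplicates(subset=["participant_id", "atc_code", "dispense_date"])


def _days_before(records: pd.DataFrame, sampling_date) -> pd.Series:
    disp = pd.to_datetime(records["dispense_date"])
    samp = pd.to_datetime(sampling_date)
    if np.ndim(samp) == 0:
        return (samp - disp).dt.days.astype(float)
    return (pd.Series(samp.values, index=records.index) - disp).dt.days.astype(float)


def count_courses(records: pd.DataFrame, sampling_date) -> pd.DataFrame:
    """Per-class course counts in the three look-back periods for one participant.

    One dispensed prescription counts as one course. Periods are half-open day
    intervals before sampling: [0, 365.25), [365.25, 1461), [1461, 2922).
    Records on/after sampling or >= 2922 days before are not counted; records
    dated after sampling are flagged in the log.

    Returns a DataFrame indexed by the 11 classes with the period columns.
    """
    out = pd.DataFrame(0, index=list(ANTIBIOTIC_CLASSES), columns=list(PERIOD_ORDER))
    if len(records) == 0:
        return out
    rec = _dedupe(records).copy()
    rec["abx_class"] = classify_atc_series(rec["atc_code"])
    rec = rec[rec["abx_class"].isin(ANTIBIOTIC_CLASSES)]
    days = _days_before(rec, sampling_date)
    n_post = int((days < 0).sum())
    if n_post:
        logger.info("count_courses: %d record(s) dated after sampling ignored", n_post)
    for period, (lo, hi) in PERIOD_BOUNDS.items():
        mask = (days >= lo) & (days < hi)
        counts = rec.loc[mask, "abx_class"].value_counts()
        out.loc[counts.index, period] += counts
    return out


def monthly_exposure(records: pd.DataFrame, sampling_date) -> np.ndarray:
    """11 x 96 binary exposure matrix for one participant.

    Month m (1-based) covers days [30.4375*(m-1), 30.4375*m) before sampling;
    a cell is 1 iff at least one record of that class falls in the month.
    """
    out = np.zeros((len(ANTIBIOTIC_CLASSES), N_MONTHS), dtype=np.int8)
    if len(records) == 0:
        return out
    rec = _dedupe(records).copy()
    rec["abx_class"] = classify_atc_series(rec["atc_code"])
    rec = rec[rec["abx_class"].isin(ANTIBIOTIC_CLASSES)]
    days = _days_before(rec, sampling_date).to_numpy()
    ok = (days >= 0) & (days < LOOKBACK_DAYS)
    month_idx = np.floor(days[ok] / DAYS_PER_MONTH).astype(int)  # 0-based
    class_idx = rec.loc[ok, "abx_class"].map(
        {c: i for i, c in enumerate(ANTIBIOTIC_CLASSES)}
    ).to_numpy()
    out[class_idx, month_idx] = 1
    return out


# ---------------------------------------------------------------------------
# Long-term-user rules (acne/rosacea and urinary-prophylaxis regimens)
# ---------------------------------------------------------------------------

RULE_METHENAMINE = "long_term_methenamine"
RULE_NITRO_TMP = "long_term_nitrofurantoin_trimethoprim"
RULE_DOXY40 = "long_term_doxycycline_40mg"
RULE_DOXY100 = "long_term_doxycycline_100mg"
RULE_TETRACYCLINE = "long_term_tetracycline_lymecycline"

# "3 months" = 91 days; "12/8/6 weeks" = 84/56/42 days.
_DOXY100_THRESHOLDS = ((84, 84.0), (56, 56.0), (42, 42.0))
_TETRA_THRESHOLDS = ((84, 42.0), (56, 28.0), (42, 21.0))


def long_term_user(records: pd.DataFrame, sampling_date) -> tuple[bool, list[str]]:
    """Detect long-term prophylactic/rosacea antibiotic regimens near sampling.

    Fires if ANY of:
      (a) a methenamine dispense within 91 days;
      (b) nitrofurantoin or trimethoprim DDD sum >= 22.5 within 84 days;
      (c) any 40 mg doxycycline dispense within 84 days;
      (d) 100 mg doxycycline DDD sums >= 84/56/42 within 84/56/42 days;
      (e) tetracycline or lymecycline DDD sums >= 42/28/21 within 84/56/42 days.

    Doxycycline records without a strength are skipped for rules (c)/(d) with
    a logged warning. Returns (flag, list of fired rule ids).
    """
    reasons: list[str] = []
    if len(records) == 0:
        return False, reasons
    rec = _dedupe(records).copy()
    code = rec["atc_code"].astype(str).str.upper()
    days = _days_before(rec, sampling_date)
    ddd = pd.to_numeric(rec.get("ddd_total", 0.0), errors="coerce").fillna(0.0)
    strength = pd.to_numeric(
        rec.get("strength_mg", pd.Series(np.nan, index=rec.index)), errors="coerce"
    )

    def window(w: int) -> pd.Series:
        return (days >= 0) & (days < w)

    if ((code == ATC_METHENAMINE) & window(91)).any():
        reasons.append(RULE_METHENAMINE)

    nit_tmp = code.str.startswith((ATC_NITROFURANTOIN, ATC_TRIMETHOPRIM))
    if ddd[nit_tmp & window(84)].sum() >= 22.5:
        reasons.append(RULE_NITRO_TMP)

    doxy = code == ATC_DOXYCYCLINE
    doxy_missing = doxy & strength.isna()
    if doxy_missing.any():
        logger.warning(
            "long_term_user: %d doxycycline record(s) without strength; "
            "40/100 mg rules skipped for those records",
            int(doxy_missing.sum()),
        )
    if (doxy & np.isclose(strength.fillna(-1.0), 40.0) & window(84)).any():
        reasons.append(RULE_DOXY40)
    doxy100 = doxy & np.isclose(strength.fillna(-1.0), 100.0)
    for w, thr in _DOXY100_THRESHOLDS:
        if ddd[doxy100 & window(w)].sum() >= thr:
            reasons.append(RULE_DOXY100)
            break
    tetra = code.str.startswith((ATC_TETRACYCLINE, ATC_LYMECYCLINE))
    for w, thr in _TETRA_THRESHOLDS:
        if ddd[tetra & window(w)].sum() >= thr:
            reasons.append(RULE_TETRACYCLINE)
            break
    return bool(reasons), reasons


def negative_control_exposure(records: pd.DataFrame, sampling_date) -> int:
    """1 iff >= 1 J01 dispense in (0, 365.25] days AFTER sampling.

    Pre-sampling records never count; used as a negative-control exposure to
    probe residual confounding.
    """
    if len(records) == 0:
        return 0
    rec = _dedupe(records)
    is_j01 = rec["atc_code"].astype(str).str.upper().str.startswith("J01")
    days_after = -_days_before(rec, sampling_date)
    return int(((days_after > 0) & (days_after <= DAYS_PER_YEAR) & is_j01).any())


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

RULE_WASHOUT = "washout"
RULE_IBD = "ibd"
RULE_PULMONARY = "chronic_pulmonary"
RULE_BETWEEN_VISITS = "dispense_between_visits"
RULE_VISIT_INTERVAL = "visit_interval_gt60d"
RULE_INCOMPLETE_HISTORY = "incomplete_register_history"

LONG_TERM_RULES = (
    RULE_METHENAMINE,
    RULE_NITRO_TMP,
    RULE_DOXY40,
    RULE_DOXY100,
    RULE_TETRACYCLINE,
)

ALL_EXCLUSION_RULES = (
    RULE_WASHOUT,
    *LONG_TERM_RULES,
    RULE_IBD,
    RULE_PULMONARY,
    RULE_BETWEEN_VISITS,
    RULE_VISIT_INTERVAL,
    RULE_INCOMPLETE_HISTORY,
)


def apply_exclusions(
    participants: pd.DataFrame,
    records: pd.DataFrame,
    washout_days: int = 30,
    register_start: date = REGISTER_START,
) -> tuple[pd.DataFrame, pd.Index]:
    """Apply the eligibility rules; return (audit report, eligible ids).

    Excludes participants with: any J01 dispense within ``washout_days``
    before sampling; a long-term-user rule fired; an IBD or chronic-pulmonary
    diagnosis flag; a dispense between the two visits; a visit interval of
    more than 60 days; or a sampling date earlier than 8 years after the
    register start (incomplete exposure history).

    ``participants`` must be indexed by participant id with columns
    ``sampling_date``, ``visit1_date``, ``visit2_date``, ``ibd``,
    ``pulmonary``. The audit report has one row per (participant, fired rule).
    A participant referenced in ``records`` but absent from the table is a
    hard error.
    """
    pids = participants.index
    unknown = set(records["participant_id"].unique()) - set(pids)
    if unknown:
        raise ValueError(
            f"records reference {len(unknown)} participant id(s) absent from "
            f"the participant table, e.g. {sorted(unknown)[:5]}"
        )

    rec = _dedupe(records).copy()
    rec["abx_class"] = classify_atc_series(rec["atc_code"])
    rec = rec[rec["atc_code"].astype(str).str.upper().str.startswith("J01")]
    rec = rec.merge(
        participants[["sampling_date", "visit1_date", "visit2_date"]],
        left_on="participant_id",
        right_index=True,
        how="left",
    )
    disp = pd.to_datetime(rec["dispense_date"])
    samp = pd.to_datetime(rec["sampling_date"])
    rec["days_before"] = (samp - disp).dt.days.astype(float)

    fired: list[tuple[str, str]] = []

    washed = rec[(rec["days_before"] >= 0) & (rec["days_before"] < washout_days)]
    fired += [(pid, RULE_WASHOUT) for pid in washed["participant_id"].unique()]

    # Long-term-user rules, vectorized over participants.
    code = rec["atc_code"].astype(str).str.upper()
    ddd = pd.to_numeric(rec.get("ddd_total", 0.0), errors="coerce").fillna(0.0)
    strength = pd.to_numeric(
        rec.get("strength_mg", pd.Series(np.nan, index=rec.index)), errors="coerce"
    )
    days = rec["days_before"]

    def _ids_any(mask: pd.Series) -> np.ndarray:
        return rec.loc[mask, "participant_id"].unique()

    def _ids_ddd(mask: pd.Series, w: int, thr: float) -> np.ndarray:
        sel = mask & (days >= 0) & (days < w)
        sums = ddd[sel].groupby(rec.loc[sel, "participant_id"]).sum()
        return sums.index[sums >= thr].to_numpy()

    fired += [
        (pid, RULE_METHENAMINE)
        for pid in _ids_any((code == ATC_METHENAMINE) & (days >= 0) & (days < 91))
    ]
    nit_tmp = code.str.startswith((ATC_NITROFURANTOIN, ATC_TRIMETHOPRIM))
    fired += [(pid, RULE_NITRO_TMP) for pid in _ids_ddd(nit_tmp, 84, 22.5)]
    doxy = code == ATC_DOXYCYCLINE
    n_missing = int((doxy & strength.isna()).sum())
    if n_missing:
        logger.warning(
            "apply_exclusions: %d doxycycline record(s) without strength; "
            "doxycycline rules skipped for those records",
            n_missing,
        )
    fired += [
        (pid, RULE_DOXY40)
        for pid in _ids_any(
            doxy & np.isclose(strength.fillna(-1.0), 40.0) & (days >= 0) & (days < 84)
        )
    ]
    doxy100 = doxy & np.isclose(strength.fillna(-1.0), 100.0)
    d100: set[str] = set()
    for w, thr in _DOXY100_THRESHOLDS:
        d100.update(_ids_ddd(doxy100, w, thr))
    fired += [(pid, RULE_DOXY100) for pid in d100]
    tetra = code.str.startswith((ATC_TETRACYCLINE, ATC_LYMECYCLINE))
    tet: set[str] = set()
    for w, thr in _TETRA_THRESHOLDS:
        tet.update(_ids_ddd(tetra, w, thr))
    fired += [(pid, RULE_TETRACYCLINE) for pid in tet]

    # Diagnosis flags.
    for col, rule in ((("ibd"), RULE_IBD), (("pulmonary"), RULE_PULMONARY)):
        if col in participants:
            flag = participants[col].astype(bool)
            fired += [(pid, rule) for pid in pids[flag]]

    # Dispense between the two visits (inclusive of visit days).
    v1 = pd.to_datetime(rec["visit1_date"])
    v2 = pd.to_datetime(rec["visit2_date"])
    between = (disp >= v1) & (disp <= v2)
    fired += [(pid, RULE_BETWEEN_VISITS) for pid in rec.loc[between, "participant_id"].unique()]

    # Visit interval > 60 days.
    interval = (
        pd.to_datetime(participants["visit2_date"]) - pd.to_datetime(participants["visit1_date"])
    ).dt.days
    fired += [(pid, RULE_VISIT_INTERVAL) for pid in pids[interval > 60]]

    # Incomplete register history: sampling earlier than 8 years after start.
    cutoff = pd.Timestamp(register_start) + pd.Timedelta(days=LOOKBACK_DAYS)
    early = pd.to_datetime(participants["sampling_date"]) < cutoff
    fired += [(pid, RULE_INCOMPLETE_HISTORY) for pid in pids[early]]

    report = pd.DataFrame(fired, columns=["participant_id", "rule"]).sort_values(
        ["participant_id", "rule"], ignore_index=True
    )
    excluded = pd.Index(report["participant_id"].unique())
    eligible = pids.difference(excluded, sort=False)
    logger.info(
        "apply_exclusions: %d of %d participants excluded (washout_days=%d)",
        len(excluded), len(pids), washout_days,
    )
    return report, eligible


# ---------------------------------------------------------------------------
# Bulk exposure construction
# ---------------------------------------------------------------------------


@dataclass
class Exposures:
    """Exposure variables for a set of participants.

    Attributes
    ----------
    counts : DataFrame indexed by participant id with the 33 course-count
        columns (class x period), the pooled per-period totals
        ``total_<period>``, and ``post_sampling_any``.
    monthly : int8 array of shape (n_participants, 11, 96); ``monthly[i, c, m]``
        is 1 iff participant i had >= 1 dispense of class c in month m+1.
    ids : participant ids in the row order of ``monthly``.
    """

    counts: pd.DataFrame
    monthly: np.ndarray
    ids: pd.Index

    def monthly_for_class(self, abx_class: str) -> np.ndarray:
        c = ANTIBIOTIC_CLASSES.index(abx_class)
        return self.monthly[:, c, :]


def build_exposures(participants: pd.DataFrame, records: pd.DataFrame) -> Exposures:
    """Vectorized course counts + monthly matrices for all participants."""
    pids = participants.index
    pos = {pid: i for i, pid in enumerate(pids)}
    cls_pos = {c: i for i, c in enumerate(ANTIBIOTIC_CLASSES)}

    counts = pd.DataFrame(0, index=pids, columns=list(EXPOSURE_COLUMNS), dtype=int)
    monthly = np.zeros((len(pids), len(ANTIBIOTIC_CLASSES), N_MONTHS), dtype=np.int8)
    counts["post_sampling_any"] = 0

    rec = _dedupe(records).copy()
    rec = rec[rec["participant_id"].isin(pids)]
    rec["abx_class"] = classify_atc_series(rec["atc_code"])
    rec = rec.merge(
        participants[["sampling_date"]], left_on="participant_id", right_index=True
    )
    days = (
        pd.to_datetime(rec["sampling_date"]) - pd.to_datetime(rec["dispense_date"])
    ).dt.days.astype(float)

    is_j01 = rec["atc_code"].astype(str).str.upper().str.startswith("J01")
    post = is_j01 & (days < 0) & (days >= -DAYS_PER_YEAR)
    counts.loc[rec.loc[post, "participant_id"].unique(), "post_sampling_any"] = 1

    rec = rec[rec["abx_class"].isin(ANTIBIOTIC_CLASSES)]
    days = days.loc[rec.index]
    in_window = (days >= 0) & (days < LOOKBACK_DAYS)
    rec = rec[in_window]
    days = days[in_window]

    month_idx = np.floor(days.to_numpy() / DAYS_PER_MONTH).astype(int)
    row_idx = rec["participant_id"].map(pos).to_numpy()
    col_idx = rec["abx_class"].map(cls_pos).to_numpy()
    monthly[row_idx, col_idx, month_idx] = 1

    period = pd.cut(
        days,
        bins=[0.0, 365.25, 1461.0, 2922.0],
        right=False,
        labels=list(PERIOD_ORDER),
    )
    if len(rec):
        label = rec["abx_class"].astype(str).to_numpy() + "_" + period.astype(str).to_numpy()
        pv = pd.crosstab(rec["participant_id"], pd.Series(label, index=rec.index))
        counts.loc[pv.index, pv.columns] = pv

    for per in PERIOD_ORDER:
        cols = [exposure_column(c, per) for c in ANTIBIOTIC_CLASSES]
        counts[f"total_{per}"] = counts[cols].sum(axis=1)

    return Exposures(counts=counts, monthly=monthly, ids=pids)
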