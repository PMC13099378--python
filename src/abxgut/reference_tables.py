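"""Published register-based tabulation of antibiotic use in three Swedish
population-based cohorts (large middle-aged cohort 1, n=8,488; older cohort
2, n=4,784; younger family-based cohort 3, n=1,707).

Embedded as plain text so that user proportions can be recomputed from the
printed user counts and checked against the printed percentages. Counts are
numbers of individuals with at least one course of the class in the period
before fecal sampling; percentages are as printed (one decimal).
"""

from __future__ import annotations

import io

import pandas as pd

COHORT_SIZES = {"cohort1": 8488, "cohort2": 4784, "cohort3": 1707}

#: Individuals by number of antibiotic courses in the past 8 years
#: (count, printed percent) per cohort for 0 / 1 / >=2 courses.
COURSE_GROUPS = """cohort\tcourses\tcount\tpct
cohort1\t0\t2573\t30.3
cohort1\t1\t1907\t22.5
cohort1\t2plus\t4008\t47.2
cohort2\t0\t1257\t26.3
cohort2\t1\t1073\t22.4
cohort2\t2plus\t2454\t51.3
cohort3\t0\t478\t28.0
cohort3\t1\t376\t22.0
cohort3\t2plus\t853\t50.0
"""

#: Users per antibiotic class and period (count, printed percent).
CLASS_PERIOD_USERS = """abx_class\tperiod\tcohort\tcount\tpct
penicillin_v\tlt1y\tcohort1\t559\t6.6
penicillin_v\t1to4y\tcohort1\t1501\t17.7
penicillin_v\t4to8y\tcohort1\t2124\t25.0
penicillin_v\tlt1y\tcohort2\t272\t5.7
penicillin_v\t1to4y\tcohort2\t915\t19.1
penicillin_v\t4to8y\tcohort2\t1266\t26.5
penicillin_v\tlt1y\tcohort3\t109\t6.4
penicillin_v\t1to4y\tcohort3\t332\t19.4
penicillin_v\t4to8y\tcohort3\t482\t28.2
tetracyclines\tlt1y\tcohort1\t287\t3.4
tetracyclines\t1to4y\tcohort1\t858\t10.1
tetracyclines\t4to8y\tcohort1\t1405\t16.6
tetracyclines\tlt1y\tcohort2\t146\t3.1
tetracyclines\t1to4y\tcohort2\t420\t8.8
tetracyclines\t4to8y\tcohort2\t704\t14.7
tetracyclines\tlt1y\tcohort3\t60\t3.5
tetracyclines\t1to4y\tcohort3\t189\t11.1
tetracyclines\t4to8y\tcohort3\t265\t15.5
penicillins_ext\tlt1y\tcohort1\t301\t3.5
penicillins_ext\t1to4y\tcohort1\t824\t9.7
penicillins_ext\t4to8y\tcohort1\t1013\t11.9
penicillins_ext\tlt1y\tcohort2\t201\t4.2
penicillins_ext\t1to4y\tcohort2\t559\t11.7
penicillins_ext\t4to8y\tcohort2\t615\t12.9
penicillins_ext\tlt1y\tcohort3\t48\t2.8
penicillins_ext\t1to4y\tcohort3\t149\t8.7
penicillins_ext\t4to8y\tcohort3\t209\t12.2
flucloxacillin\tlt1y\tcohort1\t166\t2.0
flucloxacillin\t1to4y\tcohort1\t570\t6.7
flucloxacillin\t4to8y\tcohort1\t732\t8.6
flucloxacillin\tlt1y\tcohort2\t120\t2.5
flucloxacillin\t1to4y\tcohort2\t349\t7.3
flucloxacillin\t4to8y\tcohort2\t428\t8.9
flucloxacillin\tlt1y\tcohort3\t28\t1.6
flucloxacillin\t1to4y\tcohort3\t104\t6.1
flucloxacillin\t4to8y\tcohort3\t142\t8.3
fluoroquinolones\tlt1y\tcohort1\t136\t1.6
fluoroquinolones\t1to4y\tcohort1\t384\t4.5
fluoroquinolones\t4to8y\tcohort1\t506\t6.0
fluoroquinolones\tlt1y\tcohort2\t126\t2.6
fluoroquinolones\t1to4y\tcohort2\t361\t7.5
fluoroquinolones\t4to8y\tcohort2\t480\t10.0
fluoroquinolones\tlt1y\tcohort3\t12\t0.7
fluoroquinolones\t1to4y\tcohort3\t56\t3.3
fluoroquinolones\t4to8y\tcohort3\t69\t4.0
nitrofurantoin\tlt1y\tcohort1\t138\t1.6
nitrofurantoin\t1to4y\tcohort1\t374\t4.4
nitrofurantoin\t4to8y\tcohort1\t331\t3.9
nitrofurantoin\tlt1y\tcohort2\t113\t2.4
nitrofurantoin\t1to4y\tcohort2\t288\t6.0
nitrofurantoin\t4to8y\tcohort2\t272\t5.7
nitrofurantoin\tlt1y\tcohort3\t23\t1.3
nitrofurantoin\t1to4y\tcohort3\t87\t5.1
nitrofurantoin\t4to8y\tcohort3\t61\t3.6
clindamycin\tlt1y\tcohort1\t104\t1.2
clindamycin\t1to4y\tcohort1\t298\t3.5
clindamycin\t4to8y\tcohort1\t387\t4.6
clindamycin\tlt1y\tcohort2\t37\t0.8
clindamycin\t1to4y\tcohort2\t131\t2.7
clindamycin\t4to8y\tcohort2\t160\t3.3
clindamycin\tlt1y\tcohort3\t20\t1.2
clindamycin\t1to4y\tcohort3\t64\t3.7
clindamycin\t4to8y\tcohort3\t83\t4.9
smz_tmp\tlt1y\tcohort1\t38\t0.4
smz_tmp\t1to4y\tcohort1\t142\t1.7
smz_tmp\t4to8y\tcohort1\t209\t2.5
smz_tmp\tlt1y\tcohort2\t46\t1.0
smz_tmp\t1to4y\tcohort2\t132\t2.8
smz_tmp\t4to8y\tcohort2\t196\t4.1
smz_tmp\tlt1y\tcohort3\t2\t0.1
smz_tmp\t1to4y\tcohort3\t27\t1.6
smz_tmp\t4to8y\tcohort3\t52\t3.0
cephalosporins\tlt1y\tcohort1\t46\t0.5
cephalosporins\t1to4y\tcohort1\t142\t1.7
cephalosporins\t4to8y\tcohort1\t247\t2.9
cephalosporins\tlt1y\tcohort2\t19\t0.4
cephalosporins\t1to4y\tcohort2\t52\t1.1
cephalosporins\t4to8y\tcohort2\t119\t2.5
cephalosporins\tlt1y\tcohort3\t16\t0.9
cephalosporins\t1to4y\tcohort3\t45\t2.6
cephalosporins\t4to8y\tcohort3\t77\t4.5
macrolides\tlt1y\tcohort1\t42\t0.5
macrolides\t1to4y\tcohort1\t132\t1.6
macrolides\t4to8y\tcohort1\t243\t2.9
macrolides\tlt1y\tcohort2\t12\t0.3
macrolides\t1to4y\tcohort2\t51\t1.1
macrolides\t4to8y\tcohort2\t81\t1.7
macrolides\tlt1y\tcohort3\t15\t0.9
macrolides\t1to4y\tcohort3\t42\t2.5
macrolides\t4to8y\tcohort3\t65\t3.8
amox_clav\tlt1y\tcohort1\t33\t0.4
amox_clav\t1to4y\tcohort1\t76\t0.9
amox_clav\t4to8y\tcohort1\t111\t1.3
amox_clav\tlt1y\tcohort2\t9\t0.2
amox_clav\t1to4y\tcohort2\t39\t0.8
amox_clav\t4to8y\tcohort2\t60\t1.3
amox_clav\tlt1y\tcohort3\t2\t0.1
amox_clav\t1to4y\tcohort3\t9\t0.5
amox_clav\t4to8y\tcohort3\t17\t1.0
"""


def course_groups() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(COURSE_GROUPS), sep="\t")


def class_period_users() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(CLASS_PERIOD_USERS), sep="\t")


def user_proportion(count: int, n: int) -> float:
    """Percent of participants, as printed (count / cohort size * 100)."""
    return 100.0 * count / n


def recompute_proportions() -> pd.DataFrame:
    """Recompute every printed percentage from its printed count.

    Returns the class-period table with a ``recomputed`` column (percent,
    unrounded) alongside the printed ``pct``.
    """
    t = class_period_users().copy()
    t["recomputed"] = [
        user_proportion(c, COHORT_SIZES[coh]) for c, coh in zip(t["count"], t["cohort"])
    ]
    g = course_groups().copy()
    g["recomputed"] = [
        user_proportion(c, COHORT_SIZES[coh]) for c, coh in zip(g["count"], g["cohort"])
    ]
    g = g.rename(columns={"courses": "period"})
    g.insert(0, "abx_class", "any_course_group")
    return pd.concat([t, g], ignore_index=True)


def any_user_proportion(cohort: str) -> float:
    """Recomputed percent with >= 1 antibiotic course in the past 8 years."""
    g = course_groups()
    used = g[(g["cohort"] == cohort) & (g["courses"] != "0")]["count"].sum()
    return user_proportion(int(used), COHORT_SIZES[cohort])
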