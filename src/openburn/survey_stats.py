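"""Descriptive and inferential statistics for the household plastic-waste survey.

All inferential tests run on natural-log-transformed masses because the
raw household totals are right-skewed; group differences are nevertheless
reported on the raw kg scale, matching how such surveys are usually
presented. Weekly comparisons treat the two weeks as independent samples
(a plain two-sample test, not a paired one).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import ASSET_FLAGS, EDUCATION_LEVELS, N_WEEKS, HouseholdRecord, weekly_matrix

logger = logging.getLogger(__name__)

DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class SurveySummary:
    """Headline descriptives for a survey cohort."""

    weekly_mean_sd: tuple  # 4 pairs of (mean, sd), kg/week
    per_capita_daily: tuple  # (mean, sd), kg/person/day
    burn_household_fraction: float
    burn_mass_fraction: float
    n_households: int


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a covariate test on log 4-week totals."""

    covariate: str
    test: str  # "t-test" (Welch) or "ANOVA"
    statistic: float
    p_value: float
    difference_kg: float  # raw-kg group difference (owner minus non-owner)
    n_excluded_zero: int = 0


def weekly_summary(records: Sequence[HouseholdRecord]):
    """Per-week unweighted mean and sample SD of household masses.

    Households missing a week are excluded from that week's summary (with
    a logged warning), never zero-filled.

    Returns a list of four ``(mean, sd)`` tuples in kg.
    """
    if len(records) < 2:
        raise ValueError(f"need at least 2 households, got {len(records)}")
    mat = weekly_matrix(records)
    out = []
    for w in range(N_WEEKS):
        col = mat[:, w]
        valid = col[~np.isnan(col)]
        n_missing = len(col) - len(valid)
        if n_missing:
            logger.warning("week %d: %d household(s) missing, excluded", w + 1, n_missing)
        if len(valid) < 2:
            raise ValueError(f"week {w + 1}: fewer than 2 observed households")
        out.append((float(valid.mean()), float(valid.std(ddof=1))))
    return out


def per_capita_daily(
    records: Sequence[HouseholdRecord],
    days_per_week: int = DAYS_PER_WEEK,
    burn_only: bool = False,
):
    """Mean and sample SD of household per-capita daily generation rates.

    Each household's rate is its observed total mass divided by
    (persons x days_per_week x number of observed weeks); the cohort
    statistic is the unweighted mean/SD across household rates (not pooled
    mass over pooled person-days), so the SD describes between-household
    spread. ``burn_only`` restricts to households whose primary disposal
    is burning.
    """
    subset = [r for r in records if r.burn_primary] if burn_only else list(records)
    if not subset:
        raise ValueError("no households after filtering")
    rates = []
    for rec in subset:
        weeks = rec.valid_weeks()
        if not weeks:
            raise ValueError(f"household {rec.household_id!r} has no observed weeks")
        total = sum(m for _, m in weeks)
        rates.append(total / (rec.persons * days_per_week * len(weeks)))
    rates = np.asarray(rates)
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return float(rates.mean()), sd


def _log_masses(values: np.ndarray, context: str):
    """Natural logs of positive masses; zeros/negatives dropped with a count."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    positive = values[values > 0]
    n_dropped = len(values) - len(positive)
    if n_dropped:
        logger.warning("%s: excluded %d non-positive mass(es) from log transform",
                       context, n_dropped)
    return np.log(positive), n_dropped


def log_ttest_weeks(records: Sequence[HouseholdRecord], week_a: int, week_b: int):
    """Welch two-sample two-tailed t-test between two weeks' log masses.

    Weeks are 1-based. Returns ``(difference of log-means (a - b), p_value)``.
    """
    for w in (week_a, week_b):
        if not 1 <= w <= N_WEEKS:
            raise ValueError(f"week index {w} outside 1..{N_WEEKS}")
    mat = weekly_matrix(records)
    log_a, _ = _log_masses(mat[:, week_a - 1], f"week {week_a}")
    log_b, _ = _log_masses(mat[:, week_b - 1], f"week {week_b}")
    if len(log_a) < 2 or len(log_b) < 2:
        raise ValueError("fewer than 2 positive masses in a week")
    diff = float(log_a.mean() - log_b.mean())
    if week_a == week_b:
        return 0.0, 1.0
    _, p = stats.ttest_ind(log_a, log_b, equal_var=False)
    return diff, float(p)


def group_tests(records: Sequence[HouseholdRecord], covariate: str) -> GroupTestResult:
    """Test whether a covariate relates to the 4-week total mass.

    ``education`` (four levels) -> one-way ANOVA on log totals; a binary
    asset flag -> Welch t-test on log totals. The reported difference is
    on the raw-kg scale (owner minus non-owner; for education, the mean
    absolute pairwise difference among category means).
    """
    totals = np.array([r.total_mass_kg for r in records], dtype=float)

    if covariate == "education":
        groups_raw = {}
        for rec, t in zip(records, totals):
            groups_raw.setdefault(rec.education, []).append(t)
        for level, vals in groups_raw.items():
            if len(vals) < 2:
                raise ValueError(f"education level {level!r} has fewer than 2 households")
        if len(groups_raw) < 2:
            raise ValueError("education is constant across all records")
        log_groups, dropped = [], 0
        for level in EDUCATION_LEVELS:
            if level in groups_raw:
                lg, d = _log_masses(np.asarray(groups_raw[level]), f"education={level}")
                dropped += d
                if len(lg) < 2:
                    raise ValueError(f"education level {level!r}: <2 positive masses")
                log_groups.append(lg)
        f_stat, p = stats.f_oneway(*log_groups)
        means = [float(np.mean(v)) for v in groups_raw.values()]
        diffs = [abs(a - b) for i, a in enumerate(means) for b in means[i + 1:]]
        return GroupTestResult("education", "ANOVA", float(f_stat), float(p),
                               float(np.mean(diffs)), dropped)

    if covariate not in ASSET_FLAGS:
        raise ValueError(f"unknown covariate {covariate!r}")
    flags = np.array([getattr(r, covariate) for r in records], dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError(f"covariate {covariate!r} is constant across all records")
    owners, others = totals[flags], totals[~flags]
    if len(owners) < 2 or len(others) < 2:
        raise ValueError(f"a {covariate!r} group has fewer than 2 households")
    log_own, d1 = _log_masses(owners, f"{covariate}=True")
    log_non, d2 = _log_masses(others, f"{covariate}=False")
    if len(log_own) < 2 or len(log_non) < 2:
        raise ValueError(f"a {covariate!r} group has <2 positive masses")
    t_stat, p = stats.ttest_ind(log_own, log_non, equal_var=False)
    return GroupTestResult(covariate, "t-test", float(t_stat), float(p),
                           float(owners.mean() - others.mean()), d1 + d2)


def size_correlation(records: Sequence[HouseholdRecord]):
    """Pearson correlation between household size and 4-week total mass."""
    if len(records) < 3:
        raise ValueError(f"need at least 3 households, got {len(records)}")
    persons = np.array([r.persons for r in records], dtype=float)
    totals = np.array([r.total_mass_kg for r in records], dtype=float)
    if persons.std() == 0 or totals.std() == 0:
        raise ValueError("zero variance in household size or total mass")
    r, p = stats.pearsonr(persons, totals)
    return float(r), float(p)


def burning_shares(records: Sequence[HouseholdRecord]):
    """(fraction of households burning, fraction of total mass they contribute)."""
    if not records:
        raise ValueError("empty input")
    burn = np.array([r.burn_primary for r in records], dtype=bool)
    totals = np.array([r.total_mass_kg for r in records], dtype=float)
    hh_frac = float(burn.mean())
    total = totals.sum()
    mass_frac = float(totals[burn].sum() / total) if total > 0 else hh_frac
    return hh_frac, mass_frac


def summarize(records: Sequence[HouseholdRecord]) -> SurveySummary:
    """Bundle the headline descriptives into a ``SurveySummary``."""
    hh_frac, mass_frac = burning_shares(records)
    return SurveySummary(
        weekly_mean_sd=tuple(weekly_summary(records)),
        per_capita_daily=per_capita_daily(records),
        burn_household_fraction=hh_frac,
        burn_mass_fraction=mass_frac,
        n_households=len(records),
    )


# ---------------------------------------------------------------------------
# CSV I/O

_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False,
         "no": False, "": False}


def _parse_mass(cell: str) -> float:
    return math.nan if cell.strip() == "" else float(cell)


def read_households_csv(path) -> list:
    """Load household records from the survey CSV layout.

    Expected columns: household_id, persons, week1_kg..week4_kg,
    burn_primary, education, cellphone, radio, color_tv, computer,
    internet, age (optional; empty cells = missing).
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"household_id", "persons", "burn_primary", "education"} | {
            f"week{w}_kg" for w in range(1, N_WEEKS + 1)
        }
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"households CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(HouseholdRecord(
                    household_id=row["household_id"],
                    persons=int(row["persons"]),
                    weekly_masses_kg=tuple(
                        _parse_mass(row[f"week{w}_kg"]) for w in range(1, N_WEEKS + 1)
                    ),
                    burn_primary=_BOOL[row["burn_primary"].strip().lower()],
                    education=row["education"].strip(),
                    **{a: _BOOL[row.get(a, "").strip().lower()] for a in ASSET_FLAGS},
                    respondent_age_years=(
                        float(row["age"]) if row.get("age", "").strip() else None
                    ),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"households CSV row {i}: {exc}") from exc
    return records


def write_households_csv(records: Sequence[HouseholdRecord], path) -> None:
    """Write records in the layout ``read_households_csv`` expects."""
    cols = (["household_id", "persons"]
            + [f"week{w}_kg" for w in range(1, N_WEEKS + 1)]
            + ["burn_primary", "education", *ASSET_FLAGS, "age"])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            masses = ["" if (m is None or math.isnan(m)) else repr(float(m))
                      for m in r.weekly_masses_kg]
            writer.writerow([
                r.household_id, r.persons, *masses, int(r.burn_primary), r.education,
                *(int(getattr(r, a)) for a in ASSET_FLAGS),
                "" if r.respondent_age_years is None else repr(float(r.respondent_age_years)),
            ])


def all_test_results(records: Sequence[HouseholdRecord]) -> dict:
    """Run the full battery of survey tests; returns a JSON-friendly dict."""
    out = {}
    for wa, wb in [(1, 2), (1, 3), (1, 4), (3, 4)]:
        diff, p = log_ttest_weeks(records, wa, wb)
        out[f"week{wa}_vs_week{wb}"] = {"log_mean_diff": diff, "p_value": p}
    for cov in ("education", "cellphone", "radio", "color_tv", "internet"):
        try:
            res = group_tests(records, cov)
        except ValueError as exc:
            out[cov] = {"error": str(exc)}
            continue
        out[cov] = {"test": res.test, "statistic": res.statistic,
                    "p_value": res.p_value, "difference_kg": res.difference_kg}
    r, p = size_correlation(records)
    out["household_size_correlation"] = {"pearson_r": r, "p_value": p}
    return out
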