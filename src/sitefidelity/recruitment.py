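"""Prior-reproductive-success labels across temporal scales.

A mother is a successful recruit (annual scale) when a neonate born in
year t-1 survived to 120 days.  At finer scales she has a "neonate at
heel" when the neonate was alive for at least 15 of the previous 30-day
window, or at least 7 of the previous 14-day window.  Alive-days are
counted as calendar days with any overlap of the half-open life span
[birth, end) and the window.  Censoring that leaves a rule undecidable
yields status "unknown" and the female-interval is excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

from .tracks import IntervalWindow, season_windows

__all__ = ["NeonateRecord", "RecruitmentStatus", "recruitment_status", "annual_success"]

FATES = ("died", "survived_window", "censored")
ALIVE_DAYS_REQUIRED = {"month30": 15, "biweek14": 7}
SURVIVAL_WINDOW_DAYS = 120


@dataclass(frozen=True)
class NeonateRecord:
    mother_id: str
    year: int
    birth_date: date
    end_date: date  # death, censor, or birth + 120 d for window survivors
    fate: str
    maternal_fidelity_z: float = 0.0

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.end_date < self.birth_date:
            raise ValueError(
                f"{self.mother_id} {self.year}: end before birth"
            )
        if (
            self.fate == "survived_window"
            and (self.end_date - self.birth_date).days < SURVIVAL_WINDOW_DAYS
        ):
            raise ValueError("survived_window implies alive >= 120 days")

    @property
    def days_alive_known(self) -> int:
        return (self.end_date - self.birth_date).days


@dataclass(frozen=True)
class RecruitmentStatus:
    mother_id: str
    scale: str
    year: int
    index: int
    status: str  # success / failure / unknown


def _alive_days_in_window(rec: NeonateRecord, win: IntervalWindow) -> int:
    lo = max(rec.birth_date, win.start)
    hi = min(rec.end_date, win.end)
    return max(0, (hi - lo).days)


def annual_success(rec: NeonateRecord) -> str:
    """success / failure / unknown for survival to 120 days."""
    if rec.days_alive_known >= SURVIVAL_WINDOW_DAYS:
        return "success"
    if rec.fate == "died":
        return "failure"
    return "unknown"  # censored before the rule is decidable


def recruitment_status(
    records,
    mother_id: str,
    scale: str,
    interval: IntervalWindow,
) -> RecruitmentStatus:
    """Status for the timestep *preceding* the focal interval.

    ``interval`` must already be the previous timestep (year t-1 season or
    the preceding 30/14-day window); the caller shifts indices.  A mother
    with no neonate overlapping the interval is a failure ("none").
    """
    recs = [r for r in records if r.mother_id == mother_id]
    if scale == "annual":
        cand = [r for r in recs if r.year == interval.year]
        if not cand:
            return RecruitmentStatus(mother_id, scale, interval.year, interval.index, "failure")
        statuses = {annual_success(r) for r in cand}
        status = (
            "success" if "success" in statuses
            else "unknown" if "unknown" in statuses
            else "failure"
        )
        return RecruitmentStatus(mother_id, scale, interval.year, interval.index, status)

    need = ALIVE_DAYS_REQUIRED[scale]
    overlapping = [r for r in recs if r.birth_date < interval.end and r.end_date > interval.start]
    if not overlapping:
        return RecruitmentStatus(mother_id, scale, interval.year, interval.index, "failure")
    best = "failure"
    for r in overlapping:
        alive = _alive_days_in_window(r, interval)
        if alive >= need:
            return RecruitmentStatus(mother_id, scale, interval.year, interval.index, "success")
        # censored mid-window: the neonate might have lived longer
        if r.fate == "censored" and r.end_date < interval.end:
            possible = _alive_days_in_window(
                NeonateRecord(r.mother_id, r.year, r.birth_date, interval.end, "censored"),
                interval,
            )
            if possible >= need:
                best = "unknown"
    return RecruitmentStatus(mother_id, scale, interval.year, interval.index, best)


def status_table(records, mothers, scale: str, season: tuple, years) -> list[RecruitmentStatus]:
    """Previous-timestep status for every mother x focal interval.

    Annual: focal year t is labelled by year t-1 records.  Finer scales:
    focal window i is labelled by window i-1 of the same season (the first
    window of a season is labelled by the pre-season window of the same
    nominal length ending at the season start).
    """
    out = []
    for year in years:
        wins = season_windows(year, season, scale)
        for mother in mothers:
            for win in wins:
                if scale == "annual":
                    prev = IntervalWindow(
                        "annual", year - 1, 1,
                        win.start.replace(year=year - 1),
                        win.end.replace(year=year - 1),
                        win.nominal_days,
                    )
                elif win.index == 1:
                    prev = IntervalWindow(
                        scale, year, 0,
                        win.start - timedelta(days=win.nominal_days),
                        win.start,
                        win.nominal_days,
                    )
                else:
                    prev = wins[win.index - 2]
                st = recruitment_status(records, mother, scale, prev)
                out.append(
                    RecruitmentStatus(mother, scale, win.year, win.index, st.status)
                )
    return out
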