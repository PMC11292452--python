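"""Coding of law effective dates into state-year exposure and phase-in covariates.

A law record (state, policy, effective date, optional repeal) is expanded onto a
state x year x policy grid with two covariates per cell:

``exposure``
    fraction of the calendar year the law is in force (0 before enactment,
    1 for full years in force, day-count fraction in enactment/repeal years).
``phase``
    linear ramp from 0 at implementation to 1 at the phase-in horizon
    (default 5 years), evaluated at the observation year's midpoint.

Ten policies are supported, grouped into six classes (four restrictive, two
permissive) and higher-level combinations.
"""

from __future__ import annotations

import datetime as dt
import itertools
import string
from dataclasses import dataclass, field

import pandas as pd

#: The ten policies, in canonical column order.  The first seven are
#: restrictive (their presence restricts firearms); the last three permissive.
POLICY_IDS: tuple[str, ...] = (
    "bc_dealer",
    "bc_private",
    "possess_under18",
    "purchase_under20",
    "wait_24h",
    "wait_7day",
    "child_access_storage",
    "shall_issue",
    "permitless_carry",
    "stand_your_ground",
)

RESTRICTIVE_POLICIES: tuple[str, ...] = POLICY_IDS[:7]
PERMISSIVE_POLICIES: tuple[str, ...] = POLICY_IDS[7:]

POLICY_DIRECTION: dict[str, str] = {
    **{p: "restrictive" for p in RESTRICTIVE_POLICIES},
    **{p: "permissive" for p in PERMISSIVE_POLICIES},
}

#: Conceptual classes.  Four restrictive classes, two permissive.
POLICY_CLASSES: dict[str, tuple[str, ...]] = {
    "background_checks": ("bc_dealer", "bc_private"),
    "minimum_age": ("possess_under18", "purchase_under20"),
    "waiting_periods": ("wait_24h", "wait_7day"),
    "child_access": ("child_access_storage",),
    "concealed_carry": ("shall_issue", "permitless_carry"),
    "stand_your_ground": ("stand_your_ground",),
}

RESTRICTIVE_CLASSES: tuple[str, ...] = (
    "background_checks",
    "minimum_age",
    "waiting_periods",
    "child_access",
)
PERMISSIVE_CLASSES: tuple[str, ...] = ("concealed_carry", "stand_your_ground")

#: Class -> broader combination.
CLASS_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "purchase_and_possession": ("background_checks", "minimum_age", "waiting_periods"),
    "use_and_storage": ("child_access", "concealed_carry", "stand_your_ground"),
}

DEFAULT_HORIZON: float = 5.0


class LawCodingError(ValueError):
    """Raised on invalid law records or panel construction requests."""


@dataclass(frozen=True)
class LawRecord:
    """A single policy enactment in one state.

    ``direction`` is determined by ``policy_id``; if supplied it must agree
    with the canonical direction of the policy.
    """

    state: str
    policy_id: str
    effective_date: dt.date
    repeal_date: dt.date | None = None
    direction: str = ""

    def __post_init__(self) -> None:
        if self.policy_id not in POLICY_IDS:
            raise LawCodingError(
                f"unknown policy_id {self.policy_id!r}; expected one of {POLICY_IDS}"
            )
        canonical = POLICY_DIRECTION[self.policy_id]
        if self.direction and self.direction != canonical:
            raise LawCodingError(
                f"direction {self.direction!r} inconsistent with policy "
                f"{self.policy_id!r} (canonical: {canonical!r})"
            )
        object.__setattr__(self, "direction", canonical)
        if not isinstance(self.effective_date, dt.date):
            raise LawCodingError("effective_date must be a datetime.date")
        if self.repeal_date is not None and self.repeal_date <= self.effective_date:
            raise LawCodingError(
                f"repeal_date {self.repeal_date} not after effective_date "
                f"{self.effective_date} ({self.state}/{self.policy_id})"
            )


@dataclass(frozen=True)
class ClassMap:
    """Grouping of the 10 policies into classes, combinations and the
    most-restrictive contrast signs."""

    policy_to_class: dict[str, str] = field(
        default_factory=lambda: {
            p: c for c, members in POLICY_CLASSES.items() for p in members
        }
    )
    class_to_combination: dict[str, str] = field(
        default_factory=lambda: {
            c: combo for combo, members in CLASS_COMBINATIONS.items() for c in members
        }
    )
    most_restrictive_sign: dict[str, int] = field(
        default_factory=lambda: {
            **{p: +1 for p in RESTRICTIVE_POLICIES},
            **{p: -1 for p in PERMISSIVE_POLICIES},
        }
    )

    def __post_init__(self) -> None:
        if set(self.policy_to_class) != set(POLICY_IDS):
            raise LawCodingError("policy_to_class must cover exactly the 10 policies")
        classes = set(self.policy_to_class.values())
        if len(classes) != 6:
            raise LawCodingError(f"expected 6 classes, got {len(classes)}")
        n_restrictive = sum(
            1
            for c in classes
            if all(POLICY_DIRECTION[p] == "restrictive" for p in self.class_members(c))
        )
        if n_restrictive != 4:
            raise LawCodingError("expected 4 restrictive and 2 permissive classes")
        for p, s in self.most_restrictive_sign.items():
            expected = +1 if POLICY_DIRECTION[p] == "restrictive" else -1
            if s != expected:
                raise LawCodingError(
                    f"most_restrictive sign for {p} must be {expected}, got {s}"
                )

    def class_members(self, cls: str) -> tuple[str, ...]:
        return tuple(p for p in POLICY_IDS if self.policy_to_class[p] == cls)


def _decimal_year(d: dt.date) -> float:
    """Calendar date as a fractional year (Jan 1 -> year.0); leap-aware."""
    start = dt.date(d.year, 1, 1)
    days = (dt.date(d.year + 1, 1, 1) - start).days
    return d.year + (d - start).days / days


def exposure_fraction(
    effective_date: dt.date, repeal_date: dt.date | None, year: int
) -> float:
    """Fraction of calendar ``year`` during which the law is in force.

    Day ``d`` counts as in force when ``effective_date <= d`` and, if a repeal
    exists, ``d < repeal_date``.  Leap years use actual day counts.
    """
    if repeal_date is not None and repeal_date <= effective_date:
        raise LawCodingError(
            f"repeal_date {repeal_date} not after effective_date {effective_date}"
        )
    year_start = dt.date(year, 1, 1)
    year_end = dt.date(year + 1, 1, 1)
    lo = max(effective_date, year_start)
    hi = min(repeal_date, year_end) if repeal_date is not None else year_end
    in_force = max((hi - lo).days, 0)
    return in_force / (year_end - year_start).days


def phase_in_covariate(years_since: float, horizon: float = DEFAULT_HORIZON) -> float:
    """Linear phase-in ramp: 0 at implementation, 1 at/after ``horizon`` years."""
    if horizon <= 0:
        raise LawCodingError(f"horizon must be positive, got {horizon}")
    return min(max(years_since / horizon, 0.0), 1.0)


def years_since_midpoint(effective_date: dt.date, year: int) -> float:
    """Signed years from the effective date to the observation year midpoint."""
    return (year + 0.5) - _decimal_year(effective_date)


def _check_no_overlap(records: list[LawRecord]) -> None:
    far_future = dt.date(9999, 1, 1)
    spans = sorted(
        (r.effective_date, r.repeal_date or far_future, r) for r in records
    )
    for (lo1, hi1, r1), (lo2, _, r2) in zip(spans, spans[1:]):
        if lo2 < hi1:
            raise LawCodingError(
                f"overlapping records for ({r1.state}, {r1.policy_id}): "
                f"{r1.effective_date}..{r1.repeal_date or 'open'} and "
                f"{r2.effective_date}..{r2.repeal_date or 'open'}"
            )


def build_policy_panel(
    records: list[LawRecord],
    states: list[str],
    years: list[int] | range,
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Expand law records onto the full state x year x policy grid.

    Returns a long DataFrame with columns ``state, year, policy_id, exposure,
    phase, years_since``.  ``years_since`` is measured at the year midpoint
    from the governing record's effective date (NaN where no record exists
    for that state/policy).
    """
    years = sorted(years)
    if years != list(range(years[0], years[-1] + 1)):
        raise LawCodingError("years must be contiguous")
    for r in records:
        if r.state not in states:
            raise LawCodingError(f"record state {r.state!r} not in panel states")

    by_key: dict[tuple[str, str], list[LawRecord]] = {}
    for r in records:
        by_key.setdefault((r.state, r.policy_id), []).append(r)
    for recs in by_key.values():
        _check_no_overlap(recs)

    rows = []
    for state in states:
        for year in years:
            mid = year + 0.5
            for policy in POLICY_IDS:
                recs = by_key.get((state, policy), [])
                e = sum(
                    exposure_fraction(r.effective_date, r.repeal_date, year)
                    for r in recs
                )
                gov = _governing_record(recs, mid)
                if gov is None:
                    ys = float("nan")
                    f = 0.0
                else:
                    ys = mid - _decimal_year(gov.effective_date)
                    if gov.repeal_date is not None:
                        ys = min(ys, _decimal_year(gov.repeal_date) - _decimal_year(gov.effective_date))
                    f = phase_in_covariate(ys, horizon) if e > 0 else 0.0
                rows.append((state, year, policy, e, f, ys))
    return pd.DataFrame(
        rows, columns=["state", "year", "policy_id", "exposure", "phase", "years_since"]
    )


def _governing_record(recs: list[LawRecord], mid: float) -> LawRecord | None:
    """Record whose phase-in applies at year midpoint ``mid``.

    Prefers the record active at the midpoint; otherwise the most recent
    record effective before it; otherwise the earliest upcoming one.
    """
    if not recs:
        return None
    active = [
        r
        for r in recs
        if _decimal_year(r.effective_date) <= mid
        and (r.repeal_date is None or _decimal_year(r.repeal_date) > mid)
    ]
    if active:
        return max(active, key=lambda r: r.effective_date)
    past = [r for r in recs if _decimal_year(r.effective_date) <= mid]
    if past:
        return max(past, key=lambda r: r.effective_date)
    return min(recs, key=lambda r: r.effective_date)


# ---------------------------------------------------------------------------
# CSV interfaces

def read_laws_csv(path) -> list[LawRecord]:
    """Read law records from CSV (state, policy_id, effective_date[, repeal_date])."""
    df = pd.read_csv(path, dtype=str)
    required = {"state", "policy_id", "effective_date"}
    missing = required - set(df.columns)
    if missing:
        raise LawCodingError(f"laws CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        repeal = row.get("repeal_date")
        repeal_date = (
            dt.date.fromisoformat(repeal) if isinstance(repeal, str) and repeal else None
        )
        records.append(
            LawRecord(
                state=row["state"],
                policy_id=row["policy_id"],
                effective_date=dt.date.fromisoformat(row["effective_date"]),
                repeal_date=repeal_date,
            )
        )
    return records


def write_policy_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_policy_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"state", "year", "policy_id", "exposure", "phase", "years_since"}
    missing = expected - set(df.columns)
    if missing:
        raise LawCodingError(f"policy panel CSV missing columns: {sorted(missing)}")
    return df


def synthetic_state_codes(n: int) -> list[str]:
    """``n`` distinct two-letter state codes (USPS codes first, then generated)."""
    usps = [
        "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "FL", "GA",
        "HI", "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME", "MD",
        "MA", "MI", "MN", "MS", "MO", "MT", "NE", "NV", "NH", "NJ",
        "NM", "NY", "NC", "ND", "OH", "OK", "OR", "PA", "RI", "SC",
        "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI", "WY",
    ]
    if n <= len(usps):
        return usps[:n]
    extra = (
        "".join(pair)
        for pair in itertools.product(string.ascii_uppercase, repeat=2)
    )
    codes = list(usps)
    for code in extra:
        if code not in usps:
            codes.append(code)
        if len(codes) == n:
            break
    return codes
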