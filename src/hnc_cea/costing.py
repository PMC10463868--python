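"""Bottom-up micro-costing from the societal perspective.

Per-patient cost records are aggregated into a cost table with three
groups — direct medical (visits, laboratory, diagnosis, radiotherapy),
direct non-medical (transport, lodging) and indirect (productivity loss)
— reported as per-patient means per strategy arm.  Indirect costs are
valued with the human-capital approach: days absent times the daily wage,
for the patient, an accompanying person, and any home nursing.  Amounts
recorded in Iranian Rials are converted to US dollars at a single fixed
study-period exchange rate at ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import InvalidInputError

DIRECT_MEDICAL: tuple[str, ...] = ("visits", "laboratory", "diagnosis", "radiotherapy")
DIRECT_NON_MEDICAL: tuple[str, ...] = ("transport", "lodging")
INDIRECT: tuple[str, ...] = ("productivity_loss",)
CATEGORIES: tuple[str, ...] = DIRECT_MEDICAL + DIRECT_NON_MEDICAL + INDIRECT

CURRENCIES: tuple[str, ...] = ("IRR", "USD")

#: Central Bank of Iran average rate for the study period.
DEFAULT_IRR_PER_USD = 36_692.0


@dataclass(frozen=True)
class ExchangeRate:
    """A fixed IRR-per-USD conversion rate."""

    irr_per_usd: float = DEFAULT_IRR_PER_USD

    def __post_init__(self) -> None:
        if not self.irr_per_usd > 0:
            raise InvalidInputError(
                f"exchange rate must be positive, got {self.irr_per_usd!r}"
            )


@dataclass(frozen=True)
class CostItem:
    """One recorded cost for one patient in one category."""

    patient_id: str
    category: str
    amount: float
    currency: str = "USD"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidInputError(
                f"unknown cost category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.currency not in CURRENCIES:
            raise InvalidInputError(
                f"unknown currency {self.currency!r}; expected one of {CURRENCIES}"
            )
        if not (self.amount >= 0 and math.isfinite(self.amount)):
            raise InvalidInputError(f"cost amount must be finite and >= 0, got {self.amount!r}")


@dataclass(frozen=True)
class AbsenteeismRecord:
    """Days absent and daily wages for the human-capital valuation.

    All monetary fields are in USD per day; days may be fractional.
    """

    patient_id: str
    patient_days_absent: float = 0.0
    patient_daily_wage: float = 0.0
    companion_days_absent: float = 0.0
    companion_daily_wage: float = 0.0
    home_nursing_days: float = 0.0
    nursing_daily_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "patient_days_absent",
            "patient_daily_wage",
            "companion_days_absent",
            "companion_daily_wage",
            "home_nursing_days",
            "nursing_daily_rate",
        ):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")


def convert_to_usd(amount: float, rate: ExchangeRate) -> float:
    """Convert an IRR amount to USD at the fixed study rate."""
    if not (amount >= 0 and math.isfinite(amount)):
        raise InvalidInputError(f"amount must be finite and >= 0, got {amount!r}")
    return amount / rate.irr_per_usd


def convert_to_irr(amount: float, rate: ExchangeRate) -> float:
    """Inverse of :func:`convert_to_usd` (round-trips within float precision)."""
    if not (amount >= 0 and math.isfinite(amount)):
        raise InvalidInputError(f"amount must be finite and >= 0, got {amount!r}")
    return amount * rate.irr_per_usd


def indirect_cost_human_capital(record: AbsenteeismRecord) -> float:
    """Value productivity loss as days absent times the daily wage.

    Sums the patient's own absenteeism, the companion's absenteeism, and
    home nursing days at the nursing rate.
    """
    return (
        record.patient_days_absent * record.patient_daily_wage
        + record.companion_days_absent * record.companion_daily_wage
        + record.home_nursing_days * record.nursing_daily_rate
    )


def truncate_dollars(amount: float) -> int:
    """Whole-dollar reporting figure: the integer part (floor) of ``amount``."""
    if not (amount >= 0 and math.isfinite(amount)):
        raise InvalidInputError(f"amount must be finite and >= 0, got {amount!r}")
    return int(math.floor(amount))


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient mean costs by category with group subtotals (one arm).

    Group totals are stored redundantly and checked against the category
    means at construction, so a breakdown can never be internally
    inconsistent.
    """

    per_category: Mapping[str, float]
    direct_medical_total: float
    direct_non_medical_total: float
    indirect_total: float
    grand_total: float
    n_patients: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")
        for cat, v in self.per_category.items():
            if cat not in CATEGORIES:
                raise InvalidInputError(f"unknown category {cat!r}")
            if v < 0:
                raise InvalidInputError(f"negative mean for {cat!r}")
        checks = (
            (self.direct_medical_total, sum(self.per_category.get(c, 0.0) for c in DIRECT_MEDICAL)),
            (self.direct_non_medical_total, sum(self.per_category.get(c, 0.0) for c in DIRECT_NON_MEDICAL)),
            (self.indirect_total, sum(self.per_category.get(c, 0.0) for c in INDIRECT)),
            (self.grand_total, self.direct_medical_total + self.direct_non_medical_total + self.indirect_total),
        )
        for stored, recomputed in checks:
            if abs(stored - recomputed) > 1e-9:
                raise InvalidInputError(
                    f"inconsistent totals: stored {stored!r} vs recomputed {recomputed!r}"
                )

    @classmethod
    def from_category_means(cls, per_category: Mapping[str, float], n_patients: int) -> "CostBreakdown":
        per_category = {c: float(per_category.get(c, 0.0)) for c in CATEGORIES}
        dm = sum(per_category[c] for c in DIRECT_MEDICAL)
        dnm = sum(per_category[c] for c in DIRECT_NON_MEDICAL)
        ind = sum(per_category[c] for c in INDIRECT)
        return cls(
            per_category=per_category,
            direct_medical_total=dm,
            direct_non_medical_total=dnm,
            indirect_total=ind,
            grand_total=dm + dnm + ind,
            n_patients=n_patients,
        )


def aggregate_costs(
    items: Iterable[CostItem],
    absentee: Iterable[AbsenteeismRecord] = (),
    rate: ExchangeRate | None = None,
    n_patients: int | None = None,
) -> CostBreakdown:
    """Aggregate per-patient records into per-category per-patient means.

    Parameters
    ----------
    items
        Cost items for one strategy arm.  IRR amounts are converted to USD.
    absentee
        Absenteeism records; their human-capital value is added to the
        ``productivity_loss`` category.
    rate
        Exchange rate for IRR items (default: the study-period rate).
    n_patients
        Denominator for the per-patient means.  Defaults to the number of
        distinct patient ids seen across both record collections.

    The aggregation is invariant to record order and to splitting an item
    into same-category items with the same total.
    """
    rate = rate or ExchangeRate()
    items = list(items)
    absentee = list(absentee)

    patients = {it.patient_id for it in items} | {a.patient_id for a in absentee}
    if n_patients is None:
        n_patients = len(patients)
    if n_patients < 1:
        raise InvalidInputError("aggregate_costs requires at least one patient")

    # per-category amounts are sorted before an fsum reduction so the totals
    # are exactly invariant to record order
    amounts: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for it in items:
        usd = convert_to_usd(it.amount, rate) if it.currency == "IRR" else it.amount
        amounts[it.category].append(usd)
    for rec in absentee:
        amounts["productivity_loss"].append(indirect_cost_human_capital(rec))

    means = {c: math.fsum(sorted(amounts[c])) / n_patients for c in CATEGORIES}
    return CostBreakdown.from_category_means(means, n_patients)


def check_reported_totals(
    breakdown: CostBreakdown,
    reported: Mapping[str, float],
    tolerance: float = 0.005,
) -> list[str]:
    """Flag reported figures that disagree with the recomputed breakdown.

    ``reported`` may contain any of the keys ``direct_medical_total``,
    ``direct_non_medical_total``, ``indirect_total``, ``grand_total`` or a
    category name.  Returns one message per discrepancy larger than
    ``tolerance`` dollars; the recomputed value is always the one kept.
    """
    messages: list[str] = []
    for key, claimed in reported.items():
        if key in CATEGORIES:
            actual = breakdown.per_category.get(key, 0.0)
        else:
            try:
                actual = getattr(breakdown, key)
            except AttributeError:
                raise InvalidInputError(f"unknown reported key {key!r}") from None
        if abs(actual - claimed) > tolerance:
            messages.append(
                f"{key}: reported {claimed:.2f} differs from recomputed {actual:.2f} "
                f"by {claimed - actual:+.2f}"
            )
    return messages


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_cost_items(path) -> dict[str, list[CostItem]]:
    """Read a cost CSV (``patient_id,arm,category,amount,currency``) grouped by arm."""
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str, "category": str, "currency": str})
    required = {"patient_id", "arm", "category", "amount", "currency"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"cost file missing columns {sorted(required - set(df.columns))}")
    out: dict[str, list[CostItem]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.arm, []).append(
            CostItem(row.patient_id, row.category, float(row.amount), row.currency)
        )
    return out


def read_absenteeism(path) -> dict[str, list[AbsenteeismRecord]]:
    """Read an absenteeism CSV grouped by arm.

    Columns: ``patient_id,arm,patient_days,patient_wage,companion_days,
    companion_wage,nursing_days,nursing_rate``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str})
    out: dict[str, list[AbsenteeismRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.arm, []).append(
            AbsenteeismRecord(
                patient_id=row.patient_id,
                patient_days_absent=float(row.patient_days),
                patient_daily_wage=float(row.patient_wage),
                companion_days_absent=float(row.companion_days),
                companion_daily_wage=float(row.companion_wage),
                home_nursing_days=float(row.nursing_days),
                nursing_daily_rate=float(row.nursing_rate),
            )
        )
    return out


def breakdown_frame(breakdowns: Mapping[str, CostBreakdown]) -> pd.DataFrame:
    """Cost-table-shaped frame: category rows, subtotal rows, grand total; one column per arm."""
    rows = []
    labels = (
        [("category", c) for c in DIRECT_MEDICAL]
        + [("subtotal", "direct_medical_total")]
        + [("category", c) for c in DIRECT_NON_MEDICAL]
        + [("subtotal", "direct_non_medical_total")]
        + [("category", c) for c in INDIRECT]
        + [("subtotal", "indirect_total")]
        + [("total", "grand_total")]
    )
    for kind, label in labels:
        row: dict[str, object] = {"kind": kind, "item": label}
        for arm, b in breakdowns.items():
            row[arm] = b.per_category[label] if kind == "category" else getattr(b, label)
        rows.append(row)
    return pd.DataFrame(rows)
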