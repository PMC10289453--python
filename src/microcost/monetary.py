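"""Normalization of nominal amounts to base-year (2020) USD.

Two steps, applied in order to every line item before aggregation:

1. currency conversion at the invoice date — the monthly exchange rate when
   the invoice month is known, otherwise the annual average rate;
2. inflation adjustment — compounding annual within-country inflation over
   the years strictly after the nominal year through the base year.

Amounts carry a ``normalized`` flag; normalizing twice is rejected.  The
package ships no real exchange-rate or inflation series — the published
price table is already expressed in 2020 USD — only a small documented test
table (:func:`default_test_rates`) for exercising the conversion path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .ledger import Country, MoneyAmount, ValidationError

__all__ = [
    "RateTable",
    "RateLookupError",
    "convert_to_usd",
    "inflate_to_base",
    "normalize",
    "default_test_rates",
]


class RateLookupError(KeyError):
    """A required exchange or inflation rate is absent from the table."""


@dataclass
class RateTable:
    """Exchange rates (USD per unit of currency) and annual inflation rates.

    ``fx`` keys are ``(currency, year)`` for annual averages and
    ``(currency, year, month)`` for monthly rates.  ``inflation`` keys are
    ``(country_code, year)`` with rates as decimal fractions (> -1).
    """

    fx: dict = field(default_factory=dict)
    inflation: dict = field(default_factory=dict)
    base_year: int = 2020

    def __post_init__(self) -> None:
        for key, rate in self.fx.items():
            if rate <= 0:
                raise ValidationError(f"fx rate for {key} must be > 0, got {rate}")
        for key, rate in self.inflation.items():
            if rate <= -1:
                raise ValidationError(f"inflation for {key} must be > -1, got {rate}")

    def fx_rate(self, currency: str, year: int, month: Optional[int] = None) -> float:
        if month is not None and (currency, year, month) in self.fx:
            return self.fx[(currency, year, month)]
        if (currency, year) in self.fx:
            return self.fx[(currency, year)]
        raise RateLookupError(
            f"no exchange rate for ({currency}, {year}, month={month})"
        )

    def inflation_rate(self, country: str, year: int) -> float:
        if (country, year) not in self.inflation:
            raise RateLookupError(f"no inflation rate for ({country}, {year})")
        return self.inflation[(country, year)]


def convert_to_usd(amount: MoneyAmount, rates: RateTable) -> MoneyAmount:
    """Convert a nominal amount to USD at its nominal date.

    The monthly rate is used when the amount is dated to a month, otherwise
    the annual average; USD input is returned unchanged.
    """
    if amount.currency == "USD":
        return amount
    rate = rates.fx_rate(amount.currency, amount.nominal_year, amount.nominal_month)
    return replace(amount, value=amount.value * rate, currency="USD")


def inflate_to_base(amount: MoneyAmount, rates: RateTable, country) -> MoneyAmount:
    """Express a nominal-USD amount in base-year terms by compounding annual
    within-country inflation over years in (nominal_year, base_year]."""
    if amount.currency != "USD":
        raise ValidationError("inflate_to_base expects a USD amount; convert first")
    code = country.value if isinstance(country, Country) else str(country)
    if amount.nominal_year > rates.base_year:
        raise ValidationError(
            f"nominal_year {amount.nominal_year} is after base year "
            f"{rates.base_year}; deflation is not supported"
        )
    factor = 1.0
    for year in range(amount.nominal_year + 1, rates.base_year + 1):
        factor *= 1.0 + rates.inflation_rate(code, year)
    return replace(
        amount,
        value=amount.value * factor,
        nominal_year=rates.base_year,
        nominal_month=None,
        normalized=True,
    )


def normalize(amount: MoneyAmount, rates: RateTable, country) -> MoneyAmount:
    """Full normalization: currency conversion then inflation adjustment.

    This is the single money path used by every downstream total.  An
    already-normalized amount is rejected rather than silently re-adjusted.
    """
    if amount.normalized:
        raise ValidationError("amount is already normalized to base-year USD")
    if amount.currency == "USD" and amount.nominal_year == rates.base_year:
        return replace(amount, normalized=True)
    return inflate_to_base(convert_to_usd(amount, rates), rates, country)


def default_test_rates() -> RateTable:
    """A small synthetic rate table for tests and examples.

    Order-of-magnitude realistic (KES ~100/USD, UGX ~3700/USD; low-single-digit
    annual inflation) but NOT the series used in any published analysis.
    """
    fx = {
        ("KES", 2018): 0.0099, ("KES", 2019): 0.0098, ("KES", 2020): 0.0094,
        ("KES", 2019, 6): 0.0097,
        ("UGX", 2018): 0.00027, ("UGX", 2019): 0.00027, ("UGX", 2020): 0.00027,
        ("UGX", 2019, 6): 0.000268,
    }
    inflation = {
        ("KE", 2019): 0.052, ("KE", 2020): 0.054,
        ("UG", 2019): 0.029, ("UG", 2020): 0.033,
    }
    return RateTable(fx=fx, inflation=inflation, base_year=2020)
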