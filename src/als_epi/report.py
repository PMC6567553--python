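"""Presentation-layer helpers: rounding and report-shaped tables.

All estimation happens upstream at full precision; this module only
rounds (half-up, as printed tables do) and reshapes stage outputs.
"""

from __future__ import annotations

import decimal

import pandas as pd

from .rates import RateEstimate


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.005 -> 2.01), as used in printed tables."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def format_rate(est: RateEstimate, ndigits: int = 2) -> str:
    """'2.74 (2.59-2.88)' presentation of a rate estimate."""
    r = round_half_up(est.rate, ndigits)
    lo = round_half_up(est.ci_low, ndigits)
    hi = round_half_up(est.ci_high, ndigits)
    return f"{r:.{ndigits}f} ({lo:.{ndigits}f}–{hi:.{ndigits}f})"


def incidence_summary(region_results: dict[str, dict[str, RateEstimate]]) -> pd.DataFrame:
    """Crude and adjusted rates per region, one formatted column per region.

    ``region_results`` maps region label -> {"crude", "male", "female",
    "overall"} rate estimates.
    """
    rows = {
        "Crude incidence rate (per 100,000 per year) (95% CI)": "crude",
        "Male age-adjusted incidence rate": "male",
        "Female age-adjusted incidence rate": "female",
        "Overall age- and sex-adjusted incidence rate": "overall",
    }
    out = {}
    for region, results in region_results.items():
        out[region] = {label: format_rate(results[key]) for label, key in rows.items()}
    return pd.DataFrame(out)


def prevalence_summary(series_by_scenario: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """First/last-year prevalence per scenario, by sex and overall."""
    rows = []
    for name, series in series_by_scenario.items():
        first = series.iloc[0]
        last = series.iloc[-1]
        rows.append(
            {
                "scenario": name,
                "first_year": int(first["year"]),
                "last_year": int(last["year"]),
                **{
                    f"{stratum}_{when}": round_half_up(ser[f"{stratum}_per_100k"])
                    for stratum in ("male", "female", "overall")
                    for when, ser in (("first", first), ("last", last))
                },
            }
        )
    return pd.DataFrame(rows)
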