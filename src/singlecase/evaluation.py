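"""Type I error and power estimation, overall and stratified.

Decisions are kept in a long pandas DataFrame with one row per
(graph, method): the factorial design columns, the injected SMD, the
baseline-length scheme and the analyzer's boolean effect call.  Type I
error is the proportion of null (SMD = 0) graphs flagged as showing an
effect; power is the proportion of true-effect (SMD >= 1) graphs
flagged.  Rates are exact proportions — no smoothing — with their
denominators carried alongside.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Factors a stratified report may use (ConditionSpec fields plus the
#: initial-trend tag of the trend experiment).
STRATIFIABLE_FACTORS = (
    "min_a",
    "n_b",
    "autocorr",
    "stability_threshold",
    "smd",
    "initial_trend_sign",
)

_REQUIRED_COLUMNS = {"method", "scheme", "smd", "effect"}


def _rate_row(sub: pd.DataFrame) -> dict:
    null = sub[sub["smd"] == 0]
    eff = sub[sub["smd"] >= 1]
    return {
        "type1": null["effect"].mean() if len(null) else np.nan,
        "power": eff["effect"].mean() if len(eff) else np.nan,
        "n_null": len(null),
        "n_effect": len(eff),
    }


def compute_rates(
    decisions: pd.DataFrame, stratum: str = "overall", warn_empty: bool = True
) -> pd.DataFrame:
    """Exact type-I-error and power proportions per (method, scheme).

    Returns one row per (method, scheme) with columns ``type1``,
    ``power``, ``n_null``, ``n_effect`` and a ``stratum`` label.  A side
    with an empty denominator is reported as NaN with a logged warning;
    a (method, scheme) group empty on both sides is omitted.
    """
    missing = _REQUIRED_COLUMNS - set(decisions.columns)
    if missing:
        raise ValueError(f"decisions frame is missing columns {sorted(missing)}")
    if decisions.empty:
        raise ValueError("decisions frame is empty")
    rows = []
    for (method, scheme), sub in decisions.groupby(["method", "scheme"], sort=True):
        row = _rate_row(sub)
        if row["n_null"] == 0 and row["n_effect"] == 0:
            continue
        if warn_empty and (row["n_null"] == 0 or row["n_effect"] == 0):
            logger.warning(
                "stratum %r has no %s graphs for method=%s scheme=%s",
                stratum,
                "null" if row["n_null"] == 0 else "effect",
                method,
                scheme,
            )
        rows.append({"method": method, "scheme": scheme, "stratum": stratum, **row})
    return pd.DataFrame(rows)


def stratified_report(
    decisions: pd.DataFrame, factors: Iterable[str]
) -> Mapping[str, pd.DataFrame]:
    """One rate table per design factor, with one stratum per factor level.

    The ``smd`` factor stratifies by effect size 1-5 and therefore
    reports power only (there are no null graphs inside an SMD >= 1
    stratum).
    """
    reports: dict[str, pd.DataFrame] = {}
    for factor in factors:
        if factor not in STRATIFIABLE_FACTORS:
            raise ValueError(
                f"unknown factor {factor!r}; expected one of {STRATIFIABLE_FACTORS}"
            )
        if factor not in decisions.columns:
            raise ValueError(f"decisions frame has no column {factor!r}")
        levels = decisions[factor].dropna().unique()
        if factor == "smd":
            levels = [lv for lv in levels if lv != 0]
        tables = []
        for level in sorted(levels):
            sub = decisions[decisions[factor] == level]
            if sub.empty:
                logger.warning("factor %s level %r has no decisions", factor, level)
                continue
            tables.append(
                compute_rates(
                    sub,
                    stratum=f"{factor}={level}",
                    # the effect-size table is power-only by construction
                    warn_empty=factor != "smd",
                )
            )
        reports[factor] = (
            pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        )
    return reports


def trend_direction_report(decisions: pd.DataFrame) -> pd.DataFrame:
    """Rates split by the direction of the initial baseline trend.

    Only meaningful for the trend experiment, whose graphs carry an
    ``initial_trend_sign`` tag (the sign of the OLS trend over the first
    ``min_a`` points); calling it on variability-experiment decisions is
    an error.
    """
    if (
        "initial_trend_sign" not in decisions.columns
        or decisions["initial_trend_sign"].isna().all()
    ):
        raise ValueError(
            "trend-direction analysis requires trend-experiment decisions "
            "tagged with initial_trend_sign"
        )
    return stratified_report(decisions, ["initial_trend_sign"])["initial_trend_sign"]


def round_rates(table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Rates rounded for reporting (three decimals, as conventionally printed)."""
    out = table.copy()
    for col in ("type1", "power"):
        if col in out.columns:
            out[col] = out[col].round(decimals)
    return out


def wilson_interval(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a proportion (diagnostic use)."""
    if n <= 0:
        return (np.nan, np.nan)
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def plot_rate_bars(rates: pd.DataFrame, path, title: str = "") -> None:
    """Grouped bar chart of type I error and power per method and scheme."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, metric in zip(axes, ("type1", "power")):
        pivot = rates.pivot_table(index="scheme", columns="method", values=metric)
        pivot.plot.bar(ax=ax, rot=0)
        ax.set_ylabel({"type1": "Type I error rate", "power": "Power"}[metric])
        if metric == "type1":
            ax.axhline(0.05, color="grey", linestyle="--", linewidth=1)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
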