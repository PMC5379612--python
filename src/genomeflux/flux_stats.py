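"""Normalized event rates, defense-vs-all relative rates and flux statistics.

Event totals are normalized to events per COG (gene family) per genome so
that genome clusters of different size are comparable; a defense-vs-all
relative rate divides the defense-family rate by the all-family rate for
each event type. The quartile flux classification, chi-square event
composition test and Welch test on log rate excess mirror the published
analysis of those tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .bdg_model import EVENT_TYPES, EventSummary
from .io_formats import RATIO_COLUMNS, ValidationError

logger = logging.getLogger("genomeflux")

__all__ = [
    "NormalizedRates",
    "CompositionTest",
    "normalize_events",
    "relative_rates",
    "mean_ratios",
    "count_exceeding",
    "classify_flux",
    "compare_event_composition",
    "test_rate_excess",
]


@dataclass(frozen=True)
class NormalizedRates:
    """Events per COG per genome for one family set.

    ``rates`` maps each event type to its normalized rate; ``total`` is
    the combined genome-dynamics-event rate (sum of the four types).
    """

    rates: dict[str, float]
    total: float
    label: str
    n_families: int
    n_genomes: int


def normalize_events(summary: EventSummary, label: str = "") -> NormalizedRates:
    """Normalize event totals by the number of COGs and of genomes."""
    if summary.n_families <= 0 or summary.n_genomes <= 0:
        raise ValidationError("need n_families > 0 and n_genomes > 0")
    denom = summary.n_families * summary.n_genomes
    rates = {k: v / denom for k, v in summary.as_dict().items()}
    return NormalizedRates(rates=rates, total=sum(rates.values()), label=label,
                           n_families=summary.n_families,
                           n_genomes=summary.n_genomes)


def relative_rates(ds: NormalizedRates, all_: NormalizedRates) -> pd.Series:
    """One Table 1-style row: DS rate over all-gene rate per event type.

    A ratio with a zero all-gene denominator is undefined and reported as
    NaN, never as 0 or infinity.
    """
    def ratio(num: float, den: float) -> float:
        if den <= 0:
            logger.warning("undefined ratio: zero all-gene rate")
            return np.nan
        return num / den

    values = {
        "gain_ratio": ratio(ds.rates["gain"], all_.rates["gain"]),
        "loss_ratio": ratio(ds.rates["loss"], all_.rates["loss"]),
        "expansion_ratio": ratio(ds.rates["expansion"], all_.rates["expansion"]),
        "reduction_ratio": ratio(ds.rates["reduction"], all_.rates["reduction"]),
        "all_gde_ratio": ratio(ds.total, all_.total),
    }
    return pd.Series(values, index=list(RATIO_COLUMNS))


def mean_ratios(table: pd.DataFrame) -> pd.Series:
    """Arithmetic column means of the five ratio columns (NaN excluded)."""
    if table.empty:
        raise ValidationError("empty relative-rate table")
    cols = table[list(RATIO_COLUMNS)].astype(float)
    n_missing = int(cols.isna().sum().sum())
    if n_missing:
        logger.warning("mean_ratios: excluding %d undefined cells", n_missing)
    return cols.mean(axis=0, skipna=True)


def count_exceeding(table: pd.DataFrame, column: str, threshold: float) -> int:
    """Number of rows whose *column* value strictly exceeds *threshold*."""
    if column not in table.columns:
        raise ValidationError(f"no such column: {column}")
    return int((table[column].astype(float) > threshold).sum())


def classify_flux(table: pd.DataFrame) -> pd.DataFrame:
    """Quartile classification of total flux (all-GDE ratio) per ATGC.

    Rows ranked by all-GDE ratio, ties broken by ATGC ID ascending; the
    top floor(N/4) rows are ``high``, the bottom floor(N/4) are ``low``
    and the remainder ``average``. Returns a copy of the table with a
    ``flux_class`` column, plus the quartile cutpoints as attrs.
    """
    if len(table) < 4:
        raise ValidationError("need at least 4 rows to classify flux")
    k = len(table) // 4
    order = sorted(
        table.index, key=lambda a: (-float(table.loc[a, "all_gde_ratio"]), a)
    )
    classes = pd.Series("average", index=table.index, name="flux_class")
    classes.loc[order[:k]] = "high"
    classes.loc[order[-k:]] = "low"
    out = table.copy()
    out["flux_class"] = classes
    vals = table["all_gde_ratio"].astype(float)
    out.attrs["cutpoints"] = (float(vals.quantile(0.25)), float(vals.quantile(0.75)))
    return out


@dataclass(frozen=True)
class CompositionTest:
    statistic: float
    p_value: float
    dof: int
    expected_cell_warning: bool
    table: np.ndarray


def compare_event_composition(ds: EventSummary, all_: EventSummary,
                              ) -> CompositionTest:
    """Chi-square homogeneity test of event-type composition, DS vs rest.

    Builds a 2 x 4 table of expected event counts, rounded to the nearest
    integer (posterior totals are expected counts treated as counts), for
    {defense, all-minus-defense} x {gain, loss, expansion, reduction}.
    """
    if ds.total <= 0 or all_.total <= 0:
        raise ValidationError("both summaries need positive totals")
    ds_row = np.array([ds.as_dict()[t] for t in EVENT_TYPES])
    rest_row = np.array([all_.as_dict()[t] for t in EVENT_TYPES]) - ds_row
    if (rest_row < 0).any():
        raise ValidationError("defense totals exceed the all-gene totals")
    obs = np.round(np.vstack([ds_row, rest_row])).astype(int)
    if obs.sum() == 0 or (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("degenerate composition table after rounding")
    stat, p, dof, expected = scipy.stats.chi2_contingency(obs, correction=False)
    warn = bool((expected < 1).any())
    if warn:
        logger.warning("chi-square: expected cell below 1; test unreliable")
    return CompositionTest(float(stat), float(p), int(dof), warn, obs)


def test_rate_excess(ds_rates: np.ndarray, all_rates: np.ndarray) -> float:
    """Welch two-sample t-test on log-transformed per-ATGC rates.

    Compares defense-system rates against all-gene rates across genome
    clusters for one event type; non-positive pairs are dropped with a
    warning. Returns the two-sided p-value.
    """
    ds = np.asarray(ds_rates, dtype=float)
    al = np.asarray(all_rates, dtype=float)
    if ds.shape != al.shape:
        raise ValidationError("rate vectors must be paired (equal length)")
    keep = (ds > 0) & (al > 0)
    if (~keep).any():
        logger.warning("test_rate_excess: dropping %d non-positive pairs",
                       int((~keep).sum()))
    ds, al = ds[keep], al[keep]
    if len(ds) < 3:
        raise ValidationError("fewer than 3 usable pairs")
    if np.allclose(np.log(ds), np.log(al)):
        return 1.0  # identical samples: no excess, t = 0
    res = scipy.stats.ttest_ind(np.log(ds), np.log(al), equal_var=False)
    return float(res.pvalue)
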