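"""Surveillance descriptive statistics for contaminant concentration tables.

Covers the routine food-safety summaries: substitution of left-censored
(below-LOD) measurements at half the detection limit, detection and
regulatory-exceedance rates, rice-versus-paddy 2x2 chi-square comparisons,
county/township stratified percentiles, and per-county counts of townships
with at least one exceeding sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InvalidInputError, MalformedRecordError
from .risk import ElementToxicology

__all__ = [
    "ConcentrationSample",
    "ContingencyTable2x2",
    "samples_from_frame",
    "samples_to_frame",
    "read_samples",
    "write_samples",
    "substitute_below_lod",
    "detection_and_exceedance_rates",
    "pearson_chi2_2x2",
    "stratum_percentiles",
    "township_exceedance_summary",
]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "sample_id",
    "year",
    "county",
    "township",
    "source",
    "element",
    "value",
    "below_lod",
]


@dataclass(frozen=True)
class ConcentrationSample:
    """One measured concentration with censoring flag and stratum labels.

    ``value`` is the concentration in mg/kg and is ``None`` when the
    measurement fell below the analytical LOD (``below_lod=True``).
    ``source`` distinguishes polished rice from paddy (unhusked) samples.
    """

    sample_id: str
    year: int
    county: str
    township: str
    source: str
    element: str
    value: float | None
    below_lod: bool

    def __post_init__(self) -> None:
        if self.source not in ("rice", "paddy"):
            raise MalformedRecordError(f"{self.sample_id}: source must be rice|paddy")
        if not self.below_lod and self.value is None:
            raise MalformedRecordError(f"{self.sample_id}: uncensored sample lacks a value")
        if self.value is not None and self.value < 0:
            raise MalformedRecordError(f"{self.sample_id}: negative concentration")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 exceedance table: (paddy, rice) x (exceed, not exceed)."""

    paddy_exceed: int
    paddy_ok: int
    rice_exceed: int
    rice_ok: int

    def __post_init__(self) -> None:
        if min(self.paddy_exceed, self.paddy_ok, self.rice_exceed, self.rice_ok) < 0:
            raise InvalidInputError("contingency counts must be >= 0")

    @classmethod
    def from_group_totals(
        cls, paddy_exceed: int, paddy_n: int, rice_exceed: int, rice_n: int
    ) -> "ContingencyTable2x2":
        return cls(paddy_exceed, paddy_n - paddy_exceed, rice_exceed, rice_n - rice_exceed)

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.paddy_exceed, self.paddy_ok], [self.rice_exceed, self.rice_ok]],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def samples_from_frame(df: pd.DataFrame) -> list[ConcentrationSample]:
    """Build sample records from a DataFrame with the standard columns."""
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"sample table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        value = None if pd.isna(row.value) else float(row.value)
        out.append(
            ConcentrationSample(
                sample_id=str(row.sample_id),
                year=int(row.year),
                county=str(row.county),
                township=str(row.township),
                source=str(row.source),
                element=str(row.element),
                value=value,
                below_lod=bool(row.below_lod),
            )
        )
    return out


def samples_to_frame(samples: Iterable[ConcentrationSample]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in samples], columns=SAMPLE_COLUMNS)


def read_samples(path) -> list[ConcentrationSample]:
    """Read a delimited-text concentration table (CSV with header)."""
    return samples_from_frame(pd.read_csv(path))


def write_samples(samples: Iterable[ConcentrationSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Censoring substitution and rates
# ---------------------------------------------------------------------------

def _require_single_element(samples: Sequence[ConcentrationSample], tox: ElementToxicology) -> None:
    elements = {s.element for s in samples}
    if elements - {tox.element}:
        raise InvalidInputError(
            f"samples contain elements {sorted(elements)} but toxicology is for {tox.element}"
        )


def substitute_below_lod(
    samples: Sequence[ConcentrationSample], tox: ElementToxicology
) -> np.ndarray:
    """Replace censored measurements with LOD/2; pass uncensored values through.

    The standard treatment of left-censored surveillance data: a value
    reported only as "< LOD" enters downstream statistics as half the limit
    of detection.
    """
    _require_single_element(samples, tox)
    out = np.empty(len(samples))
    n_cens = 0
    for i, s in enumerate(samples):
        if s.below_lod:
            out[i] = tox.lod / 2.0
            n_cens += 1
        else:
            if s.value is None:
                raise MalformedRecordError(f"{s.sample_id}: uncensored sample lacks a value")
            out[i] = s.value
    if n_cens:
        logger.info("substituted %d/%d censored %s values at LOD/2 = %g mg/kg",
                    n_cens, len(samples), tox.element, tox.lod / 2.0)
    return out


def detection_and_exceedance_rates(
    samples: Sequence[ConcentrationSample], tox: ElementToxicology
) -> dict:
    """Detection/exceedance summary for one element (surveillance-table row).

    Detection means the measurement was above the LOD (uncensored);
    exceedance means strictly above the regulatory limit.  Mean and SD are
    computed on half-LOD-substituted values; the maximum is over detected
    values only.
    """
    if len(samples) == 0:
        raise InvalidInputError("empty sample list")
    _require_single_element(samples, tox)
    n = len(samples)
    detected = sum(1 for s in samples if not s.below_lod)
    exceeded = sum(1 for s in samples if not s.below_lod and s.value > tox.limit)
    substituted = substitute_below_lod(samples, tox)
    detected_values = [s.value for s in samples if not s.below_lod]
    return {
        "element": tox.element,
        "n": n,
        "detected": detected,
        "detection_fraction": detected / n,
        "detection_rate_pct": 100.0 * detected / n,
        "exceeded": exceeded,
        "exceedance_fraction": exceeded / n,
        "exceedance_rate_pct": 100.0 * exceeded / n,
        "max_mg_kg": max(detected_values) if detected_values else np.nan,
        "mean_mg_kg": float(np.mean(substituted)),
        "sd_mg_kg": float(np.std(substituted, ddof=1)) if n > 1 else np.nan,
        "limit_mg_kg": tox.limit,
        "lod_mg_kg": tox.lod,
    }


def pearson_chi2_2x2(table: ContingencyTable2x2, yates: bool = False) -> dict:
    """Uncorrected Pearson chi-square on a 2x2 table, 1 degree of freedom.

    The uncorrected statistic is the default (it is what routine
    surveillance comparisons report); Yates continuity correction is
    available behind ``yates=True`` but never applied implicitly.
    """
    obs = table.as_array()
    if obs.sum() <= 0:
        raise InvalidInputError("contingency table has zero grand total")
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected == 0):
        raise DegenerateDataError("expected cell count of zero; table is degenerate")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=yates)
    return {"statistic": float(chi2), "p_value": float(p), "dof": int(dof)}


# ---------------------------------------------------------------------------
# Stratified percentiles and township exceedance
# ---------------------------------------------------------------------------

def stratum_percentiles(
    values: Sequence[float],
    strata: Sequence[str],
    probs: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Per-stratum percentiles (linear interpolation between order statistics).

    ``values`` are half-LOD-substituted concentrations aligned with the
    stratum labels.  Returns one row per stratum plus a ``Total`` row, with
    one ``P{100p}`` column per requested probability.  Empty strata are
    omitted (a warning is logged upstream when labels disappear).
    """
    if len(values) != len(strata):
        raise InvalidInputError("values and strata must be aligned")
    if len(values) == 0:
        return pd.DataFrame(columns=["stratum", "n", *[f"P{int(100*p)}" for p in probs]])
    df = pd.DataFrame({"stratum": list(strata), "value": np.asarray(values, dtype=float)})
    rows = []
    for name, grp in df.groupby("stratum", sort=True):
        qs = np.percentile(grp["value"], [100 * p for p in probs], method="linear")
        rows.append({"stratum": name, "n": len(grp), **{f"P{int(100*p)}": q for p, q in zip(probs, qs)}})
    qs = np.percentile(df["value"], [100 * p for p in probs], method="linear")
    rows.append({"stratum": "Total", "n": len(df), **{f"P{int(100*p)}": q for p, q in zip(probs, qs)}})
    return pd.DataFrame(rows)


def township_exceedance_summary(
    samples: Sequence[ConcentrationSample], tox: ElementToxicology
) -> pd.DataFrame:
    """Per-county counts of townships tested and townships with >= 1 exceedance."""
    _require_single_element(samples, tox)
    if not samples:
        return pd.DataFrame(columns=["county", "townships_tested", "townships_exceeding"])
    records: dict[str, dict[str, bool]] = {}
    for s in samples:
        townships = records.setdefault(s.county, {})
        exceeds = (not s.below_lod) and s.value > tox.limit
        townships[s.township] = townships.get(s.township, False) or exceeds
    rows = [
        {
            "county": county,
            "townships_tested": len(tw),
            "townships_exceeding": sum(tw.values()),
        }
        for county, tw in sorted(records.items())
    ]
    return pd.DataFrame(rows)
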