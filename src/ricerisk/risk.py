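"""USEPA-style deterministic dose and risk equations for dietary heavy-metal exposure.

The exposure model is the standard ingestion-route chain

    ADD = C x IR / BW              average daily dose, mg/(kg*day)
    THQ = ADD / RfD                target hazard quotient (non-carcinogenic)
    HI  = sum THQ                  hazard index across co-occurring elements
    CR  = ADD x SF                 carcinogenic risk
    CCR = sum CR                   cumulative carcinogenic risk
    EMI = ADD x (ED*EF/AT) x 30 x 1000   estimated monthly intake, ug/(kg BW*month)

with C the contaminant concentration in rice (mg/kg), IR the daily rice
ingestion rate (kg/day) and BW the body weight (kg).  EMI is compared against
the JECFA provisional tolerable monthly intake (PTMI, 25 ug/kg BW/month for
cadmium); the ratio EMI/PTMI is itself a hazard quotient.

Toxicological constants (oral reference doses, cancer slope factors,
regulatory limits, analytical LODs) for the four elements surveyed in Nanning
rice -- Pb, Cd, inorganic As and total Hg -- ship as a small fixture table.
The cadmium reference dose is deliberately stored in two variants (``table1``
= 0.0005 and ``mc`` = 0.001 mg/(kg*day)) because published point and
probabilistic assessments of this dataset are internally consistent only
under different choices; every risk operation therefore takes its dose
threshold explicitly, and named presets bundle the (BW, RfD-variant) pairs
that reproduce each published result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .errors import (
    InvalidInputError,
    InvalidToxicologyError,
    NotCarcinogenicError,
)

__all__ = [
    "ElementToxicology",
    "ExposureInput",
    "EmiSettings",
    "RiskResult",
    "RiskPreset",
    "PRESETS",
    "load_toxicology",
    "compute_add",
    "compute_thq",
    "compute_hi",
    "compute_cr",
    "compute_ccr",
    "classify_carcinogenic_risk",
    "compute_emi",
    "thq_from_emi",
    "deterministic_assessment",
]

ELEMENTS = ("Pb", "Cd", "iAs", "Hg")

#: Carcinogenic-risk band edges (dimensionless lifetime risk).
CR_LOW_EDGE = 1.0e-6
CR_HIGH_EDGE = 1.0e-4


@dataclass(frozen=True)
class ElementToxicology:
    """Toxicological constants for one element.

    rfd / rfd_mc: oral reference dose variants, mg/(kg*day); ``rfd`` is the
    tabulated value, ``rfd_mc`` the variant used by the probabilistic
    assessment (cadmium only).  sf: cancer slope factor, (kg*day)/mg, ``None``
    for non-carcinogens.  limit: regulatory maximum in rice, mg/kg.  lod:
    analytical limit of detection, mg/kg (``lod_alt`` is the alternate set
    printed alongside the surveillance summary).  ptmi: provisional tolerable
    monthly intake, ug/(kg BW*month), cadmium only.
    """

    element: str
    rfd: float
    sf: float | None
    limit: float
    lod: float
    lod_alt: float | None = None
    rfd_mc: float | None = None
    ptmi: float | None = None

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise InvalidToxicologyError(f"{self.element}: rfd must be > 0")
        if self.sf is not None and self.sf < 0:
            raise InvalidToxicologyError(f"{self.element}: sf must be >= 0")
        if self.limit <= 0 or self.lod <= 0:
            raise InvalidToxicologyError(f"{self.element}: limit and lod must be > 0")
        if self.ptmi is not None and self.ptmi <= 0:
            raise InvalidToxicologyError(f"{self.element}: ptmi must be > 0")

    def rfd_variant(self, variant: str) -> float:
        """Return the requested reference-dose variant (``table1`` or ``mc``)."""
        if variant == "table1":
            return self.rfd
        if variant == "mc":
            return self.rfd_mc if self.rfd_mc is not None else self.rfd
        raise InvalidToxicologyError(f"unknown rfd variant {variant!r}")


@dataclass(frozen=True)
class ExposureInput:
    """The (C, IR, BW) triple entering the dose equation.

    c: concentration in rice, mg/kg.  ir: ingestion rate, kg/day (survey
    files carry g/day; conversion happens once at ingestion).  bw: body
    weight, kg.
    """

    c: float
    ir: float
    bw: float

    def __post_init__(self) -> None:
        if self.c < 0 or self.ir < 0:
            raise InvalidInputError("concentration and intake must be >= 0")
        if self.bw <= 0:
            raise InvalidInputError("body weight must be > 0")


@dataclass(frozen=True)
class EmiSettings:
    """Exposure-duration bookkeeping for the monthly-intake conversion.

    For lifetime exposure ED*EF/AT = 1 and EMI reduces to
    ADD x 30 days/month x 1000 ug/mg.
    """

    ed_years: float = 70.0
    ef_days_per_year: float = 365.0
    at_days: float = 70.0 * 365.0
    days_per_month: float = 30.0
    ug_per_mg: float = 1000.0

    def __post_init__(self) -> None:
        if self.ed_years <= 0:
            raise InvalidInputError("exposure duration must be > 0")
        if not 0 < self.ef_days_per_year <= 366:
            raise InvalidInputError("exposure frequency must be in (0, 366] days/year")
        if self.at_days <= 0:
            raise InvalidInputError("averaging time must be > 0")

    @property
    def duration_factor(self) -> float:
        return self.ed_years * self.ef_days_per_year / self.at_days


@dataclass(frozen=True)
class RiskPreset:
    """A named (body weight, RfD variant) pair reproducing a published scenario."""

    name: str
    bw: float
    rfd_variant: str


#: ``deterministic-2020`` backs the point assessment (implied BW ~ 64 kg,
#: tabulated RfDs); ``mc-2020`` backs the Monte Carlo assessment (BW = 60 kg,
#: cadmium RfD 0.001 mg/(kg*day)).
PRESETS: Mapping[str, RiskPreset] = {
    "deterministic-2020": RiskPreset("deterministic-2020", bw=64.0, rfd_variant="table1"),
    "mc-2020": RiskPreset("mc-2020", bw=60.0, rfd_variant="mc"),
}


def load_toxicology(path: str | None = None) -> dict[str, ElementToxicology]:
    """Load the element toxicology table (the shipped fixture by default).

    The file is delimited text with columns element, rfd_table1, rfd_mc, sf,
    limit_mg_kg, lod_mg_kg, lod_alt_mg_kg, ptmi; empty cells mean "not
    applicable".
    """
    if path is None:
        with resources.files("ricerisk.data").joinpath("toxicology.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out: dict[str, ElementToxicology] = {}
    for row in df.itertuples(index=False):
        out[row.element] = ElementToxicology(
            element=row.element,
            rfd=float(row.rfd_table1),
            rfd_mc=None if pd.isna(row.rfd_mc) else float(row.rfd_mc),
            sf=None if pd.isna(row.sf) else float(row.sf),
            limit=float(row.limit_mg_kg),
            lod=float(row.lod_mg_kg),
            lod_alt=None if pd.isna(row.lod_alt_mg_kg) else float(row.lod_alt_mg_kg),
            ptmi=None if pd.isna(row.ptmi) else float(row.ptmi),
        )
    return out


# ---------------------------------------------------------------------------
# Dose and risk operations
# ---------------------------------------------------------------------------

def compute_add(inp: ExposureInput) -> float:
    """Average daily dose ADD = C * IR / BW, mg/(kg*day)."""
    return inp.c * inp.ir / inp.bw


def compute_thq(add: float, rfd: float) -> float:
    """Target hazard quotient THQ = ADD / RfD; THQ >= 1 flags potential concern."""
    if rfd <= 0:
        raise InvalidToxicologyError("rfd must be > 0")
    if add < 0:
        raise InvalidInputError("add must be >= 0")
    return add / rfd


def compute_hi(thqs: Sequence[float]) -> float:
    """Hazard index HI = sum of THQs across elements."""
    if len(thqs) == 0:
        raise InvalidInputError("hazard index of an empty THQ list is undefined")
    if any(t < 0 for t in thqs):
        raise InvalidInputError("THQ values must be >= 0")
    return float(sum(thqs))


def compute_cr(add: float, sf: float | None) -> float:
    """Carcinogenic risk CR = ADD * SF (lifetime excess cancer probability)."""
    if sf is None:
        raise NotCarcinogenicError("element has no cancer slope factor")
    if add < 0 or sf < 0:
        raise InvalidInputError("add and sf must be >= 0")
    return add * sf


def compute_ccr(crs: Sequence[float]) -> float:
    """Cumulative carcinogenic risk CCR = sum of CRs."""
    if len(crs) == 0:
        raise InvalidInputError("cumulative risk of an empty CR list is undefined")
    if any(c < 0 for c in crs):
        raise InvalidInputError("CR values must be >= 0")
    return float(sum(crs))


def classify_carcinogenic_risk(cr: float) -> str:
    """Band a (cumulative) carcinogenic risk.

    Closed interval [1e-6, 1e-4] -> ``potential``; below -> ``low``;
    above -> ``high``.
    """
    if cr < 0:
        raise InvalidInputError("carcinogenic risk must be >= 0")
    if cr < CR_LOW_EDGE:
        return "low"
    if cr <= CR_HIGH_EDGE:
        return "potential"
    return "high"


def compute_emi(add: float, settings: EmiSettings = EmiSettings()) -> float:
    """Estimated monthly intake, ug/(kg BW*month).

    EMI = ADD x (ED*EF/AT) x 30 days/month x 1000 ug/mg; with the lifetime
    defaults the duration factor is 1 and EMI = ADD x 30000.
    """
    if add < 0:
        raise InvalidInputError("add must be >= 0")
    return add * settings.duration_factor * settings.days_per_month * settings.ug_per_mg


def thq_from_emi(emi: float, ptmi: float) -> float:
    """Hazard quotient of a monthly intake against its tolerable monthly intake."""
    if ptmi <= 0:
        raise InvalidToxicologyError("ptmi must be > 0")
    if emi < 0:
        raise InvalidInputError("emi must be >= 0")
    return emi / ptmi


# ---------------------------------------------------------------------------
# Result container and the multi-element deterministic block
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


@dataclass
class RiskResult:
    """Full-precision risk metrics for a set of elements, plus display rounding.

    ``add``/``thq``/``cr``/``emi`` map element -> value; ``hi`` and ``ccr``
    are the corresponding sums.  Display convention: risks to 3 significant
    figures, hazard quotients to 2 decimals.
    """

    add: dict[str, float]
    thq: dict[str, float]
    hi: float
    cr: dict[str, float] = field(default_factory=dict)
    ccr: float | None = None
    emi: dict[str, float] = field(default_factory=dict)
    carcinogenic_band: str | None = None

    def display(self) -> dict:
        out: dict = {
            "ADD [mg/(kg*day)]": {k: _round_sig(v) for k, v in self.add.items()},
            "THQ": {k: round(v, 2) for k, v in self.thq.items()},
            "HI": round(self.hi, 2),
        }
        if self.cr:
            out["CR"] = {k: _round_sig(v) for k, v in self.cr.items()}
            out["CCR"] = _round_sig(self.ccr)
            out["carcinogenic band"] = self.carcinogenic_band
        if self.emi:
            out["EMI [ug/(kg BW*month)]"] = {k: round(v, 2) for k, v in self.emi.items()}
        return out


def deterministic_assessment(
    concentrations: Mapping[str, float],
    ir_kg_day: float,
    bw: float,
    toxicology: Mapping[str, ElementToxicology],
    rfd_variant: str = "table1",
    emi_settings: EmiSettings = EmiSettings(),
) -> RiskResult:
    """Point assessment of all elements at fixed concentration/intake/body weight.

    Computes ADD and THQ per element, HI over all of them, CR/CCR over the
    elements carrying a slope factor, and EMI for elements with a PTMI
    (cadmium).  ``rfd_variant`` selects the reference-dose convention.
    """
    if not concentrations:
        raise InvalidInputError("no concentrations supplied")
    add: dict[str, float] = {}
    thq: dict[str, float] = {}
    cr: dict[str, float] = {}
    emi: dict[str, float] = {}
    for el, c in concentrations.items():
        if el not in toxicology:
            raise InvalidToxicologyError(f"no toxicology entry for element {el!r}")
        tox = toxicology[el]
        a = compute_add(ExposureInput(c=c, ir=ir_kg_day, bw=bw))
        add[el] = a
        thq[el] = compute_thq(a, tox.rfd_variant(rfd_variant))
        if tox.sf is not None and el != "Cd":
            # Cd carries a slope factor but its published exposure metrics are
            # THQ/HI/EMI only; CR is assessed for Pb and iAs.
            cr[el] = compute_cr(a, tox.sf)
        if tox.ptmi is not None:
            emi[el] = compute_emi(a, emi_settings)
    hi = compute_hi(list(thq.values()))
    ccr = compute_ccr(list(cr.values())) if cr else None
    band = classify_carcinogenic_risk(ccr) if ccr is not None else None
    return RiskResult(add=add, thq=thq, hi=hi, cr=cr, ccr=ccr, emi=emi, carcinogenic_band=band)
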