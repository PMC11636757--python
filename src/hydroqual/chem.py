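"""Core water-chemistry data model, unit conversions, and guideline screening.

The central container is a tidy :class:`pandas.DataFrame` with one row per
well-season record (columns named as :class:`WaterSample` fields).  Single
records can be validated through the :class:`WaterSample` dataclass.

Concentrations are mg/L throughout; EC is µS/cm; hardness is expressed as
mg/L CaCO3 equivalent.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Season",
    "IonSpec",
    "ION_REGISTRY",
    "CATIONS",
    "ANIONS",
    "WaterSample",
    "StandardsTable",
    "ScreeningReport",
    "mg_to_meq",
    "mg_to_mmol",
    "total_hardness",
    "charge_balance_error",
    "screen",
    "read_samples",
    "samples_to_frame",
    "round_half_up",
]


class Season(str, enum.Enum):
    """Sampling campaign: wet (spring recharge) or dry (late summer)."""

    WET = "wet"
    DRY = "dry"


@dataclass(frozen=True)
class IonSpec:
    """An ion's conversion constants: IUPAC molar mass and absolute valence."""

    name: str
    molar_mass: float  # g/mol
    valence: int  # equivalents per mol, absolute charge

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar mass of {self.name} must be > 0")
        if self.valence < 1:
            raise ValueError(f"valence of {self.name} must be >= 1")


ION_REGISTRY: dict[str, IonSpec] = {
    "Ca": IonSpec("Ca", 40.078, 2),
    "Mg": IonSpec("Mg", 24.305, 2),
    "Na": IonSpec("Na", 22.990, 1),
    "K": IonSpec("K", 39.098, 1),
    "HCO3": IonSpec("HCO3", 61.016, 1),
    "CO3": IonSpec("CO3", 60.008, 2),
    "Cl": IonSpec("Cl", 35.453, 1),
    "SO4": IonSpec("SO4", 96.06, 2),
    "NO3": IonSpec("NO3", 62.004, 1),
}

CATIONS: tuple[str, ...] = ("Ca", "Mg", "Na", "K")
ANIONS: tuple[str, ...] = ("HCO3", "CO3", "Cl", "SO4", "NO3")

#: Major-ion concentration columns expected in a samples table.
ION_COLUMNS: tuple[str, ...] = ("Ca", "Mg", "Na", "K", "HCO3", "Cl", "SO4", "NO3")

#: Non-ion physicochemical columns.
FIELD_COLUMNS: tuple[str, ...] = ("pH", "EC", "TDS", "TH", "BOD", "COD")


def _ion(ion: str | IonSpec) -> IonSpec:
    if isinstance(ion, IonSpec):
        return ion
    try:
        return ION_REGISTRY[ion]
    except KeyError:
        raise KeyError(f"unknown ion {ion!r}; register an IonSpec for it") from None


def mg_to_meq(conc, ion: str | IonSpec):
    """Convert mg/L to meq/L: ``conc * valence / molar_mass``.

    Linear in ``conc``; accepts scalars or arrays.  Raises ``KeyError`` for an
    unregistered ion name.
    """
    spec = _ion(ion)
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = conc * spec.valence / spec.molar_mass
    return float(out) if out.ndim == 0 else out


def mg_to_mmol(conc, ion: str | IonSpec):
    """Convert mg/L to mmol/L (molar, not equivalent, concentration)."""
    spec = _ion(ion)
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = conc / spec.molar_mass
    return float(out) if out.ndim == 0 else out


def total_hardness(ca, mg):
    """Total hardness as mg/L CaCO3: ``2.497*Ca + 4.115*Mg`` (Ca, Mg in mg/L)."""
    ca = np.asarray(ca, dtype=float)
    mg = np.asarray(mg, dtype=float)
    if np.any(ca < 0) or np.any(mg < 0):
        raise ValueError("Ca and Mg must be >= 0")
    out = 2.497 * ca + 4.115 * mg
    return float(out) if out.ndim == 0 else out


def charge_balance_error(sample: Mapping[str, float]) -> float:
    """Charge-balance error in percent.

    CBE = 100 * (sum cations - sum anions) / (sum cations + sum anions), in
    meq/L.  ``|CBE| > 10`` conventionally flags a questionable analysis; the
    caller decides what to do with it.  An all-zero ion vector is undefined
    and raises ``ValueError``.
    """
    cat = sum(mg_to_meq(float(sample.get(i, 0.0) or 0.0), i) for i in CATIONS)
    an = sum(mg_to_meq(float(sample.get(i, 0.0) or 0.0), i) for i in ANIONS)
    if cat + an == 0:
        raise ValueError("all-zero ion vector: charge balance undefined")
    cbe = 100.0 * (cat - an) / (cat + an)
    return float(np.clip(cbe, -100.0, 100.0))  # guard one-ulp overshoot


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as report tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class WaterSample:
    """One well x one season record of field and laboratory parameters."""

    well_id: str
    season: Season
    x: float
    y: float
    pH: float
    EC: float
    TDS: float
    BOD: float
    COD: float
    Ca: float
    Mg: float
    Na: float
    K: float
    HCO3: float
    Cl: float
    SO4: float
    NO3: float
    CO3: float = 0.0
    TH: float | None = None
    depth_m: float | None = None
    lulc_tag: str | None = None

    def __post_init__(self) -> None:
        self.season = Season(self.season)
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"{self.well_id}: pH {self.pH} outside [0, 14]")
        for name in ("EC", "TDS", "BOD", "COD", "CO3", *ION_COLUMNS):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{self.well_id}: {name} = {v} < 0")
        if self.TH is not None and self.TH < 0:
            raise ValueError(f"{self.well_id}: TH = {self.TH} < 0")

    @property
    def th(self) -> float:
        """Measured TH if present, otherwise computed from Ca and Mg."""
        if self.TH is not None and not pd.isna(self.TH):
            return float(self.TH)
        return total_hardness(self.Ca, self.Mg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["season"] = self.season.value
        return d


def samples_to_frame(samples: Iterable[WaterSample]) -> pd.DataFrame:
    """Assemble validated samples into the tidy table the pipeline consumes."""
    return pd.DataFrame([s.to_dict() for s in samples])


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a samples CSV (one row per well-season) and validate it.

    Required columns: well_id, season, x, y plus the physicochemical columns.
    TH and depth_m are optional; a missing TH column is added as NaN (it is
    computed on demand, never imputed into the table).
    """
    df = pd.read_csv(path)
    required = ["well_id", "season", "x", "y", "pH", "EC", "TDS", "BOD", "COD", *ION_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"samples file missing columns: {missing}")
    bad = set(df["season"].unique()) - {s.value for s in Season}
    if bad:
        raise ValueError(f"unknown season tags: {sorted(bad)}")
    conc_cols = [c for c in (*ION_COLUMNS, "EC", "TDS", "BOD", "COD", "TH") if c in df.columns]
    neg = (df[conc_cols] < 0).any()
    if neg.any():
        raise ValueError(f"negative concentrations in columns: {list(neg[neg].index)}")
    if ((df["pH"] < 0) | (df["pH"] > 14)).any():
        raise ValueError("pH outside [0, 14]")
    if "TH" not in df.columns:
        df["TH"] = np.nan
    if "CO3" not in df.columns:
        df["CO3"] = 0.0
    return df


# --- guideline screening -----------------------------------------------------

#: Drinking-water limits (mg/L unless noted).  pH is handled as a band.
WHO_LIMITS: dict[str, float] = {
    "EC": 1500.0,  # µS/cm
    "TDS": 1000.0,
    "TH": 500.0,
    "BOD": 5.0,
    "COD": 20.0,
    "Ca": 200.0,
    "Mg": 150.0,
    "Na": 200.0,
    "K": 12.0,
    "HCO3": 500.0,
    "Cl": 250.0,
    "SO4": 250.0,
    "NO3": 50.0,
}

PH_BAND: tuple[float, float] = (6.5, 8.5)


@dataclass
class StandardsTable:
    """Parameter -> permissible limit registry with a special pH band.

    Comparison against a limit is strict ``>``: a value exactly at its limit
    passes.  The pH band is inclusive on both ends.
    """

    limits: dict[str, float] = field(default_factory=lambda: dict(WHO_LIMITS))
    ph_band: tuple[float, float] = PH_BAND

    def __post_init__(self) -> None:
        for p, s in self.limits.items():
            if s <= 0:
                raise ValueError(f"limit for {p} must be positive, got {s}")
        lo, hi = self.ph_band
        if not lo < hi:
            raise ValueError("pH band lower bound must be below upper bound")

    @classmethod
    def who_defaults(cls) -> "StandardsTable":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "StandardsTable":
        """Load limits from a YAML/JSON mapping; key ``pH`` may be a 2-list."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        band = tuple(raw.pop("pH", PH_BAND))
        return cls(limits={str(k): float(v) for k, v in raw.items()}, ph_band=band)

    def limit(self, parameter: str) -> float:
        return self.limits[parameter]

    def exceeds(self, parameter: str, value: float) -> bool:
        """Strict comparison; pH exceeds when outside the inclusive band."""
        if parameter == "pH":
            lo, hi = self.ph_band
            return value < lo or value > hi
        return value > self.limits[parameter]


@dataclass
class ScreeningReport:
    """Per-sample exceedance flags plus per-season summary fractions."""

    flags: pd.DataFrame  # well_id, season, parameter, value, limit, status
    summary: pd.DataFrame  # season, parameter, n, n_exceed, pct_exceed, pct_within

    def exceedances(self, well_id: str, season: str) -> list[str]:
        f = self.flags
        m = (f["well_id"] == well_id) & (f["season"] == season) & (f["status"] == "exceeds")
        return sorted(f.loc[m, "parameter"])

    def to_csv(self, path: str | Path) -> None:
        self.flags.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "flags": self.flags.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def screen(
    df: pd.DataFrame,
    standards: StandardsTable | None = None,
    parameters: Sequence[str] | None = None,
) -> ScreeningReport:
    """Screen every sample against drinking-water limits.

    Missing values are reported with status ``not screened`` rather than
    silently passed.  TH is computed from Ca and Mg where the column is null.
    """
    standards = standards or StandardsTable.who_defaults()
    if parameters is None:
        parameters = ["pH"] + [p for p in standards.limits if p in df.columns]
    rows = []
    for _, rec in df.iterrows():
        for p in parameters:
            value = rec.get(p, np.nan)
            if p == "TH" and pd.isna(value):
                value = total_hardness(rec["Ca"], rec["Mg"])
            if p == "pH":
                limit = standards.ph_band[1]
            elif p in standards.limits:
                limit = standards.limits[p]
            else:
                limit = np.nan
            if pd.isna(value) or pd.isna(limit):
                status = "not screened"
            elif standards.exceeds(p, float(value)):
                status = "exceeds"
            else:
                status = "within"
            rows.append(
                {
                    "well_id": rec["well_id"],
                    "season": rec["season"],
                    "parameter": p,
                    "value": value,
                    "limit": limit,
                    "status": status,
                }
            )
    flags = pd.DataFrame(rows)

    summ = []
    for (season, p), grp in flags.groupby(["season", "parameter"], sort=True):
        screened = grp[grp["status"] != "not screened"]
        n = len(screened)
        n_exc = int((screened["status"] == "exceeds").sum())
        pct_exc = round_half_up(100.0 * n_exc / n) if n else np.nan
        pct_within = round_half_up(100.0 * (n - n_exc) / n) if n else np.nan
        summ.append(
            {
                "season": season,
                "parameter": p,
                "n": n,
                "n_exceed": n_exc,
                "pct_exceed": pct_exc,
                "pct_within": pct_within,
            }
        )
    return ScreeningReport(flags=flags, summary=pd.DataFrame(summ))
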