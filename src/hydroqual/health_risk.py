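"""Non-carcinogenic nitrate health risk via drinking-water ingestion.

USEPA-style deterministic exposure model.  For a receptor group with water
intake rate IRW (L/day), exposure frequency EF (days/year), exposure
duration ED (years), body weight BW (kg) and averaging time AT (days), the
chronic daily intake of a contaminant at concentration Cw (mg/L) is

    CDI = Cw * IRW * EF * ED / (BW * AT) = Cw * k,

with the effective ingestion rate k = IRW*EF*ED/(BW*AT) in L/(kg*day).
The hazard quotient is HQ = CDI / RfD and the hazard index HI is the sum of
HQs over contaminants (equal to HQ for nitrate alone).  HI is categorised
as negligible (< 0.1), low [0.1, 1), medium [1, 4) or high (>= 4).

Default profiles for adults, children and infants are specified by their
effective rates k, anchored to reference hazard-index values at the survey's
maximum wet-season nitrate concentration; a full IRW/EF/ED/BW/AT quintuple,
when supplied, overrides k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RFD_NITRATE",
    "HI_CATEGORIES",
    "ExposureProfile",
    "RiskResult",
    "default_profiles",
    "cdi",
    "hazard",
    "calibrate_effective_rate",
    "categorize",
    "assess",
    "population_summary",
]

#: Oral reference dose for nitrate, mg/kg/day.
RFD_NITRATE: float = 1.6

#: Left-closed HI category bounds.
HI_CATEGORIES: tuple[tuple[float, str], ...] = (
    (0.1, "negligible"),
    (1.0, "low"),
    (4.0, "medium"),
    (float("inf"), "high"),
)


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-group exposure parameters.

    Either supply the full quintuple (irw, ef, ed, bw, at) or an effective
    rate ``k_override``; the quintuple takes precedence when complete.
    """

    group: str
    irw: float | None = None  # L/day
    ef: float | None = None  # days/year
    ed: float | None = None  # years
    bw: float | None = None  # kg
    at: float | None = None  # days
    k_override: float | None = None  # L/(kg*day)

    def __post_init__(self) -> None:
        quintuple = (self.irw, self.ef, self.ed, self.bw, self.at)
        if all(v is not None for v in quintuple):
            if any(v <= 0 for v in quintuple):  # type: ignore[operator]
                raise ValueError(f"{self.group}: exposure parameters must be > 0")
        elif self.k_override is None:
            raise ValueError(
                f"{self.group}: supply either the full IRW/EF/ED/BW/AT quintuple "
                "or an effective rate k"
            )
        elif self.k_override <= 0:
            raise ValueError(f"{self.group}: effective rate k must be > 0")

    @property
    def k(self) -> float:
        """Effective ingestion rate IRW*EF*ED/(BW*AT), L/(kg*day)."""
        quintuple = (self.irw, self.ef, self.ed, self.bw, self.at)
        if all(v is not None for v in quintuple):
            return self.irw * self.ef * self.ed / (self.bw * self.at)  # type: ignore[operator]
        return float(self.k_override)  # type: ignore[arg-type]


def calibrate_effective_rate(hi_ref: float, cw_ref: float, rfd: float = RFD_NITRATE) -> float:
    """Effective rate k that reproduces a reference HI at a reference Cw.

    Because HI is linear in concentration for fixed exposure parameters,
    k = HI_ref * RfD / Cw_ref; attaching this k to a profile makes
    :func:`hazard` return exactly ``hi_ref`` at ``cw_ref``.
    """
    if hi_ref <= 0 or cw_ref <= 0 or rfd <= 0:
        raise ValueError("hi_ref, cw_ref and rfd must all be > 0")
    return hi_ref * rfd / cw_ref


# Anchors: survey-maximum wet-season HI per group at the wet-season nitrate
# maximum of 61 mg/L (adults 1.45, children 1.80, infants 1.91).
_DEFAULT_ANCHORS: dict[str, float] = {"adults": 1.45, "children": 1.80, "infants": 1.91}
_ANCHOR_CW: float = 61.0


def default_profiles() -> dict[str, ExposureProfile]:
    """Calibrated default profiles; by construction k_infants > k_children > k_adults."""
    return {
        group: ExposureProfile(
            group=group,
            k_override=calibrate_effective_rate(hi, _ANCHOR_CW, RFD_NITRATE),
        )
        for group, hi in _DEFAULT_ANCHORS.items()
    }


def cdi(cw: float, profile: ExposureProfile) -> float:
    """Chronic daily intake, mg/kg/day; linear in the concentration."""
    if cw < 0:
        raise ValueError("concentration must be >= 0")
    return cw * profile.k


def categorize(hi: float) -> str:
    """HI category with left-closed boundaries at 0.1, 1 and 4."""
    if hi < 0:
        raise ValueError("HI must be >= 0")
    for bound, label in HI_CATEGORIES:
        if hi < bound:
            return label
    return HI_CATEGORIES[-1][1]


@dataclass(frozen=True)
class RiskResult:
    """CDI/HQ/HI for one well-season-group combination."""

    well_id: str | None
    season: str | None
    group: str
    cdi: float
    hq: float
    hi: float
    category: str


def hazard(
    cw: float,
    profile: ExposureProfile,
    rfd: float = RFD_NITRATE,
    well_id: str | None = None,
    season: str | None = None,
) -> RiskResult:
    """Hazard quotient and index for a single contaminant concentration."""
    if rfd <= 0:
        raise ValueError("RfD must be > 0")
    intake = cdi(cw, profile)
    hq = intake / rfd
    return RiskResult(
        well_id=well_id,
        season=season,
        group=profile.group,
        cdi=intake,
        hq=hq,
        hi=hq,  # single contaminant: HI = HQ
        category=categorize(hq),
    )


def hazard_index(hqs: Iterable[float]) -> float:
    """HI as the sum of hazard quotients over contaminants."""
    return float(sum(hqs))


def assess(
    df: pd.DataFrame,
    profiles: Mapping[str, ExposureProfile] | None = None,
    rfd: float = RFD_NITRATE,
    concentration_col: str = "NO3",
) -> pd.DataFrame:
    """Risk table over all samples and receptor groups.

    Returns one row per (well, season, group) with CDI, HQ, HI and category.
    """
    profiles = profiles or default_profiles()
    rows = []
    for _, rec in df.iterrows():
        for group, prof in profiles.items():
            r = hazard(
                float(rec[concentration_col]),
                prof,
                rfd=rfd,
                well_id=str(rec.get("well_id")),
                season=str(rec.get("season")),
            )
            rows.append(
                {
                    "well_id": r.well_id,
                    "season": r.season,
                    "group": group,
                    "CDI": r.cdi,
                    "HQ": r.hq,
                    "HI": r.hi,
                    "category": r.category,
                }
            )
    return pd.DataFrame(rows)


def population_summary(
    risk: pd.DataFrame, threshold: float = 1.0
) -> dict:
    """Exceedance fractions and HI statistics per season and receptor group.

    Returns per (season, group): n, min/mean/max HI, the fraction of wells
    with HI strictly above ``threshold`` (in percent, two decimals), plus a
    per-season ordering of groups by mean HI (descending).
    """
    from .chem import round_half_up

    out: dict = {"threshold": threshold, "seasons": {}}
    for season, sgrp in risk.groupby("season", sort=True):
        season_entry: dict = {"groups": {}}
        means = {}
        for group, grp in sgrp.groupby("group", sort=True):
            hi = grp["HI"].to_numpy(dtype=float)
            means[group] = hi.mean()
            season_entry["groups"][group] = {
                "n": int(len(hi)),
                "min_HI": float(hi.min()),
                "mean_HI": float(hi.mean()),
                "max_HI": float(hi.max()),
                "pct_above": round_half_up(100.0 * float((hi > threshold).mean())),
            }
        season_entry["ordering_by_mean_HI"] = sorted(means, key=means.get, reverse=True)
        out["seasons"][str(season)] = season_entry
    return out
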