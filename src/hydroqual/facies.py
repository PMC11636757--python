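"""Hydrochemical facies classification and ionic-ratio source diagnostics.

Implements the rectangular Chadha facies diagram (milliequivalent-percentage
differences of cations and anions), the TDS-TH water-class quadrant, molar
ion-ratio panels with qualitative source labels, and per-season Pearson
correlations used to diagnose anthropogenic nitrate inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .chem import mg_to_meq, mg_to_mmol, total_hardness

__all__ = [
    "ChadhaPoint",
    "RatioPanel",
    "chadha_coordinates",
    "tds_th_class",
    "ratio_panel",
    "source_labels",
    "season_correlations",
    "assign_end_member",
    "facies_table",
    "plot_chadha",
]

#: Ions entering the Chadha axes.  The anion denominator is the sum of the
#: four axis anions (weak-acid HCO3+CO3 and strong-acid Cl+SO4); nitrate does
#: not enter the diagram.
_CHADHA_CATIONS = ("Ca", "Mg", "Na", "K")
_CHADHA_ANIONS = ("HCO3", "CO3", "Cl", "SO4")

#: Water types of the four quadrants, keyed by (sign x > 0, sign y > 0).
_ZONE_BY_SIGNS = {
    (True, True): 5,   # Ca-Mg-HCO3, temporary hardness / recharging water
    (True, False): 6,  # Ca-Mg-Cl, reverse ion exchange, permanent hardness
    (False, False): 7,  # Na-Cl, seawater-like / end-stage
    (False, True): 8,  # Na-HCO3, base ion exchange
}

ZONE_LABELS = {
    5: "Ca-Mg-HCO3 (temporary hardness)",
    6: "Ca-Mg-Cl (reverse ion exchange)",
    7: "Na-Cl",
    8: "Na-HCO3",
}


@dataclass(frozen=True)
class ChadhaPoint:
    """Position on the Chadha rectangle plus its facies class.

    ``x`` is the meq-% difference (Ca+Mg) - (Na+K) over total cations;
    ``y`` is the meq-% difference (CO3+HCO3) - (Cl+SO4) over the axis anions.
    ``quadrant_zone`` is the primary class (fields 5-8); ``axis_flags`` are
    the half-plane dominance fields 1-4 (1 alkaline earths, 2 alkalis,
    3 weak acids, 4 strong acids), consistent with the signs of x and y.
    Points on an axis (x == 0 or y == 0) are assigned to the positive side.
    """

    x: float
    y: float
    quadrant_zone: int
    axis_flags: frozenset[int]

    @property
    def zone_label(self) -> str:
        return ZONE_LABELS[self.quadrant_zone]

    def near_anion_equiline(self, band: float = 5.0) -> bool:
        """True when |y| is within ``band`` meq-% of zero.

        Samples in this band sit on the weak-acid/strong-acid balance line;
        diagram-based groupings sometimes class them with the half-plane
        dominance field rather than a quadrant, so the band is the
        implementable surrogate for that visual judgement.
        """
        return abs(self.y) <= band


def chadha_coordinates(sample: Mapping[str, float]) -> ChadhaPoint:
    """Project one sample onto the Chadha rectangle.

    Raises ``ValueError`` if either the cation or the axis-anion meq sum is
    zero (the percentages are undefined).
    """
    cat = {i: mg_to_meq(float(sample.get(i, 0.0) or 0.0), i) for i in _CHADHA_CATIONS}
    an = {i: mg_to_meq(float(sample.get(i, 0.0) or 0.0), i) for i in _CHADHA_ANIONS}
    cat_sum = sum(cat.values())
    an_sum = sum(an.values())
    if cat_sum <= 0 or an_sum <= 0:
        raise ValueError("Chadha coordinates undefined: zero meq sum")
    x = 100.0 * ((cat["Ca"] + cat["Mg"]) - (cat["Na"] + cat["K"])) / cat_sum
    y = 100.0 * ((an["HCO3"] + an["CO3"]) - (an["Cl"] + an["SO4"])) / an_sum
    zone = _ZONE_BY_SIGNS[(x >= 0, y >= 0)]
    flags = {1 if x >= 0 else 2, 3 if y >= 0 else 4}
    return ChadhaPoint(x=x, y=y, quadrant_zone=zone, axis_flags=frozenset(flags))


def tds_th_class(
    tds: float,
    th: float,
    th_threshold: float = 180.0,
    tds_threshold: float | None = 1000.0,
    paper_mode: bool = False,
) -> str:
    """Quadrant water class from TDS and hardness.

    Soft/hard splits at ``th_threshold`` (mg/L CaCO3), fresh/brackish at
    ``tds_threshold`` (mg/L); values exactly at a threshold go to the upper
    class.  ``paper_mode=True`` drops the TDS split and labels every sample
    brackish, reproducing survey reports that class low-TDS hard waters as
    "hard brackish" on the TH axis alone.
    """
    hardness = "hard" if th >= th_threshold else "soft"
    if paper_mode or tds_threshold is None:
        salinity = "brackish"
    else:
        salinity = "brackish" if tds >= tds_threshold else "fresh"
    return f"{hardness}-{salinity}"


@dataclass
class RatioPanel:
    """Per-sample molar ratios (plus one meq-sum ratio) with failure reasons.

    ``ratios`` maps ratio name -> value or ``None``; a ``None`` entry has an
    explanation in ``reasons`` (e.g. a zero denominator) and is never
    reported as infinity.
    """

    ratios: dict[str, float | None] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float | None:
        return self.ratios[key]


_MOLAR_RATIOS = {
    "Na/Cl": ("Na", "Cl"),
    "Ca/SO4": ("Ca", "SO4"),
    "Ca/HCO3": ("Ca", "HCO3"),
    "Mg/Na": ("Mg", "Na"),
    "Ca/Na": ("Ca", "Na"),
    "HCO3/Na": ("HCO3", "Na"),
    "NO3/Na": ("NO3", "Na"),
    "Cl/Na": ("Cl", "Na"),
    "SO4/Na": ("SO4", "Na"),
}


def ratio_panel(sample: Mapping[str, float]) -> RatioPanel:
    """Compute the diagnostic molar ratios for one sample.

    All ratios are molar (mmol/mmol) except ``(Ca+Mg)/(HCO3+SO4)`` which is
    on the equivalent (meq/meq) scale, as used on carbonate-vs-gypsum
    equiline plots.
    """
    panel = RatioPanel()
    for name, (num, den) in _MOLAR_RATIOS.items():
        n = mg_to_mmol(float(sample.get(num, 0.0) or 0.0), num)
        d = mg_to_mmol(float(sample.get(den, 0.0) or 0.0), den)
        if d == 0:
            panel.ratios[name] = None
            panel.reasons[name] = f"zero denominator ({den})"
        else:
            panel.ratios[name] = n / d
    num = mg_to_meq(float(sample.get("Ca", 0.0) or 0.0), "Ca") + mg_to_meq(
        float(sample.get("Mg", 0.0) or 0.0), "Mg"
    )
    den = mg_to_meq(float(sample.get("HCO3", 0.0) or 0.0), "HCO3") + mg_to_meq(
        float(sample.get("SO4", 0.0) or 0.0), "SO4"
    )
    key = "(Ca+Mg)/(HCO3+SO4)"
    if den == 0:
        panel.ratios[key] = None
        panel.reasons[key] = "zero denominator (HCO3+SO4)"
    else:
        panel.ratios[key] = num / den
    return panel


def source_labels(panel: RatioPanel, equiline_band: float = 0.05) -> set[str]:
    """Deterministic qualitative source labels from a ratio panel.

    * Na/Cl > 1: sodium in excess of halite stoichiometry -> silicate
      weathering and/or cation exchange; Na/Cl < 1: chloride excess ->
      anthropogenic input or reverse ion exchange.
    * (Ca+Mg)/(HCO3+SO4) meq ratio above 1: carbonate dissolution dominant;
      below 1: silicate weathering influence; within ``equiline_band`` of 1:
      mixed carbonate + evaporite dissolution.
    * Ca/HCO3 molar ratio in [0.25, 0.5] (between the 1:4 and 1:2 lines):
      calcite dissolution driven by carbonic acid alone.

    Ratios that are ``None`` contribute no label for their axis.
    """
    labels: set[str] = set()
    na_cl = panel.ratios.get("Na/Cl")
    if na_cl is not None:
        if na_cl > 1:
            labels.add("silicate-weathering/ion-exchange")
        elif na_cl < 1:
            labels.add("anthropogenic/reverse-exchange")
        else:
            labels.add("halite-dissolution")
    eq = panel.ratios.get("(Ca+Mg)/(HCO3+SO4)")
    if eq is not None:
        if abs(eq - 1.0) <= equiline_band:
            labels.add("carbonate+evaporite-mixing")
        elif eq > 1:
            labels.add("carbonate-dissolution-dominant")
        else:
            labels.add("silicate-weathering-influence")
    ca_hco3 = panel.ratios.get("Ca/HCO3")
    if ca_hco3 is not None and 0.25 <= ca_hco3 <= 0.5:
        labels.add("carbonic-acid calcite dissolution")
    return labels


#: Riverine end-member compositions (molar ratios to Na) used to attribute
#: samples on Ca/Na vs Mg/Na and Ca/Na vs HCO3/Na mixing plots.  These are
#: the classic global-survey values; the diagram boxes in regional studies
#: are rarely tabulated, so the registry is configurable.
END_MEMBERS: dict[str, dict[str, float]] = {
    "carbonate": {"Ca/Na": 50.0, "Mg/Na": 10.0, "HCO3/Na": 120.0},
    "silicate": {"Ca/Na": 0.35, "Mg/Na": 0.24, "HCO3/Na": 2.0},
}


def assign_end_member(
    panel: RatioPanel,
    end_members: Mapping[str, Mapping[str, float]] = END_MEMBERS,
) -> str | None:
    """Nearest end-member in log-ratio space, or ``None`` if ratios missing.

    This is a reconstruction of mixing-plot group membership, not a measured
    quantity: distance is Euclidean over log10 of the available Na-normalised
    ratios.
    """
    keys = ("Ca/Na", "Mg/Na", "HCO3/Na")
    vals = {k: panel.ratios.get(k) for k in keys}
    usable = [k for k, v in vals.items() if v is not None and v > 0]
    if not usable:
        return None
    best, best_d = None, math.inf
    for name, em in end_members.items():
        d = sum((math.log10(vals[k]) - math.log10(em[k])) ** 2 for k in usable)
        if d < best_d:
            best, best_d = name, d
    return best


def season_correlations(df: pd.DataFrame) -> dict[str, dict[str, float | None]]:
    """Per-season Pearson r of NO3 with Cl and with TDS.

    Returns ``{season: {"NO3_Cl": r, "NO3_TDS": r}}``; a zero-variance vector
    or fewer than 3 samples yields ``None`` for that entry.
    """
    out: dict[str, dict[str, float | None]] = {}
    for season, grp in df.groupby("season", sort=True):
        entry: dict[str, float | None] = {}
        for key, col in (("NO3_Cl", "Cl"), ("NO3_TDS", "TDS")):
            a = grp["NO3"].to_numpy(dtype=float)
            b = grp[col].to_numpy(dtype=float)
            if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
                entry[key] = None
            else:
                entry[key] = float(stats.pearsonr(a, b).statistic)
        out[str(season)] = entry
    return out


def facies_table(df: pd.DataFrame, paper_mode_tds: bool = False) -> pd.DataFrame:
    """Per-sample facies summary: Chadha coordinates/zone, water class, ratios."""
    rows = []
    for _, rec in df.iterrows():
        point = chadha_coordinates(rec)
        th = rec.get("TH")
        if pd.isna(th):
            th = total_hardness(rec["Ca"], rec["Mg"])
        panel = ratio_panel(rec)
        rows.append(
            {
                "well_id": rec["well_id"],
                "season": rec["season"],
                "chadha_x": point.x,
                "chadha_y": point.y,
                "zone": point.quadrant_zone,
                "zone_label": point.zone_label,
                "water_class": tds_th_class(rec["TDS"], float(th), paper_mode=paper_mode_tds),
                "end_member": assign_end_member(panel),
                "labels": ";".join(sorted(source_labels(panel))),
                **{f"r_{k.replace('/', '_')}": v for k, v in panel.ratios.items()},
            }
        )
    return pd.DataFrame(rows)


def plot_chadha(df: pd.DataFrame, path: str | Path) -> None:
    """Render the Chadha rectangle with one marker per sample (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for season, grp in df.groupby("season"):
        pts = [chadha_coordinates(rec) for _, rec in grp.iterrows()]
        ax.scatter([p.x for p in pts], [p.y for p in pts], label=str(season), s=25)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlim(-100, 100)
    ax.set_ylim(-100, 100)
    ax.set_xlabel("(Ca+Mg) - (Na+K), meq %")
    ax.set_ylabel("(CO3+HCO3) - (Cl+SO4), meq %")
    for zone, (zx, zy) in {5: (50, 50), 6: (50, -50), 7: (-50, -50), 8: (-50, 50)}.items():
        ax.annotate(str(zone), (zx, zy), color="grey", fontsize=14, ha="center")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
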