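"""Synthetic two-season groundwater survey generator.

Emulates the statistical structure a 27-well, wet/dry-season hydrochemical
survey of a semi-arid alluvial aquifer: every parameter is drawn from a
bounded (scaled Beta) marginal matching the survey's printed per-season
minimum / maximum / mean, nitrate co-varies with chloride and TDS through a
Gaussian copula calibrated to target Pearson correlations, and named wells
carry their documented roles (seven nitrate-exceedance wells per season,
three hardness-exceedance wells in the wet season, one soft-water well at
the dry-season hardness minimum).

The generated table matches summary structure only; it is not a
reconstruction of any real per-well measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chem import Season

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "TABLE_STATS",
    "WELLS",
    "EXCEEDANCE_WELLS",
    "TH_EXCEEDANCE_WELLS_WET",
    "SOFT_WELL",
    "EWQI_WELLS",
    "fit_marginal",
    "generate",
    "write_samples",
    "fixture_small",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Bounded marginal for one parameter in one season.

    Sampled as min + (max-min) * Beta(a, b) with mean matching:
    a/(a+b) = (mean-min)/(max-min), and a + b = ``conc`` (the concentration,
    i.e. inverse dispersion, of the Beta).  A degenerate spec (min == max)
    yields the constant.
    """

    name: str
    season: str
    min: float
    max: float
    mean: float
    conc: float = 4.0

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"{self.name}/{self.season}: mean {self.mean} outside [{self.min}, {self.max}]"
            )
        if self.conc <= 0:
            raise ValueError("Beta concentration must be > 0")

    @property
    def degenerate(self) -> bool:
        return self.min == self.max


class _ScaledBeta:
    """Frozen sampler on [min, max] with the spec's target mean."""

    def __init__(self, spec: MarginalSpec) -> None:
        self.spec = spec
        if not spec.degenerate:
            f = (spec.mean - spec.min) / (spec.max - spec.min)
            f = min(max(f, 1e-6), 1 - 1e-6)
            self.a = f * spec.conc
            self.b = (1.0 - f) * spec.conc

    def ppf(self, u):
        s = self.spec
        if s.degenerate:
            return np.full_like(np.asarray(u, dtype=float), s.min)
        return s.min + (s.max - s.min) * stats.beta.ppf(u, self.a, self.b)

    def cdf(self, x):
        s = self.spec
        if s.degenerate:
            return np.where(np.asarray(x, dtype=float) < s.min, 0.0, 1.0)
        return stats.beta.cdf((np.asarray(x, dtype=float) - s.min) / (s.max - s.min), self.a, self.b)

    def rvs(self, n: int, rng: np.random.Generator):
        return self.ppf(rng.random(n))


def fit_marginal(spec: MarginalSpec) -> _ScaledBeta:
    """Build the scaled-Beta sampler for a marginal spec."""
    return _ScaledBeta(spec)


# --- printed per-season summary statistics: (min, max, mean) -----------------

TABLE_STATS: dict[str, dict[str, tuple[float, float, float]]] = {
    "wet": {
        "pH": (7.10, 8.00, 7.53),
        "EC": (366.0, 917.0, 533.81),
        "TDS": (183.0, 459.0, 267.19),
        "TH": (240.17, 882.87, 359.29),
        "BOD": (5.20, 8.30, 7.04),
        "COD": (11.10, 15.90, 13.21),
        "Ca": (11.0, 222.0, 82.78),
        "Mg": (22.0, 104.0, 37.15),
        "Na": (9.0, 68.0, 32.41),
        "K": (0.30, 1.90, 1.09),
        "HCO3": (134.0, 361.0, 235.00),
        "Cl": (10.0, 65.0, 29.89),
        "SO4": (5.0, 91.0, 32.67),
        "NO3": (14.0, 61.0, 35.70),
    },
    "dry": {
        "pH": (7.10, 7.90, 7.38),
        "EC": (346.0, 882.0, 524.96),
        "TDS": (173.0, 441.0, 262.67),
        "TH": (174.282, 497.48, 320.05),
        "BOD": (6.00, 9.10, 7.80),
        "COD": (12.30, 20.70, 16.17),
        "Ca": (27.0, 145.0, 82.37),
        "Mg": (15.0, 41.0, 27.85),
        "Na": (9.0, 68.0, 33.41),
        "K": (0.30, 3.06, 1.27),
        "HCO3": (95.0, 328.0, 197.00),
        "Cl": (12.0, 58.0, 28.11),
        "SO4": (6.0, 132.0, 35.04),
        "NO3": (12.0, 60.0, 29.00),
    },
}

#: 27 well identifiers; the named ones carry documented roles.
WELLS: tuple[str, ...] = (
    "Ka-15", "Sa-10", "Na-16", "Ku-11", "Gl-3", "As-2", "Is-1", "Tu-4",
    "Ba-37", "Bn-19", "Ha-7", "Gr-2", "Da-23", "Ro-12",
    "Er-5", "Er-8", "Bn-6", "Sh-9", "Qa-13", "Za-14", "Ko-17", "Mi-18",
    "Ta-20", "Pe-21", "Se-22", "Ay-24", "Du-25",
)

#: Wells with NO3 > 50 mg/L, per season.
EXCEEDANCE_WELLS: dict[str, tuple[str, ...]] = {
    "wet": ("Ka-15", "Sa-10", "Na-16", "Ku-11", "Gl-3", "As-2", "Is-1"),
    "dry": ("Ka-15", "Tu-4", "Na-16", "Ku-11", "Gl-3", "As-2", "Is-1"),
}

#: Wells with wet-season TH above the 500 mg/L limit.
TH_EXCEEDANCE_WELLS_WET: tuple[str, ...] = ("Sa-10", "Gl-3", "As-2")

#: The single soft-water well; holds the dry-season TH minimum.
SOFT_WELL: str = "Ba-37"

#: Eight-well subset used for the EWQI assessment.
EWQI_WELLS: tuple[str, ...] = (
    "Bn-19", "Ka-15", "Na-16", "Sa-10", "Ku-11", "Gl-3", "As-2", "Is-1",
)

#: Soft/hard hardness split (mg/L CaCO3) honoured by the dry-season roles.
_TH_SOFT_SPLIT: float = 180.0
_TH_LIMIT: float = 500.0
_NO3_LIMIT: float = 50.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic survey.

    Defaults are the survey conditions themselves: 27 wells, two seasons,
    printed marginals, NO3-Cl Pearson targets 0.16 (wet) / 0.64 (dry), a
    positive NO3-TDS association, and the named-well roles.
    """

    n_wells: int = 27
    seasons: tuple[str, ...] = ("wet", "dry")
    wells: tuple[str, ...] = WELLS
    stats: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: TABLE_STATS
    )
    r_no3_cl: Mapping[str, float] = field(
        default_factory=lambda: {"wet": 0.16, "dry": 0.64}
    )
    r_no3_tds: Mapping[str, float] = field(
        default_factory=lambda: {"wet": 0.45, "dry": 0.45}
    )
    exceedance_wells: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(EXCEEDANCE_WELLS)
    )
    th_exceedance_wells_wet: tuple[str, ...] = TH_EXCEEDANCE_WELLS_WET
    soft_well: str = SOFT_WELL
    beta_conc: float = 4.0
    seed: int = 0
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 10000.0, 10000.0)
    depth_range: tuple[float, float] = (160.0, 350.0)

    def __post_init__(self) -> None:
        for season, r in {**dict(self.r_no3_cl), **dict(self.r_no3_tds)}.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation for {season} must be in (-1, 1)")
        for season in self.seasons:
            exc = self.exceedance_wells.get(season, ())
            if len(exc) > self.n_wells:
                raise ValueError("more exceedance wells than wells")
            unknown = set(exc) - set(self.wells)
            if unknown:
                raise ValueError(f"unknown exceedance wells: {sorted(unknown)}")

    def marginal(self, param: str, season: str) -> MarginalSpec:
        lo, hi, mean = self.stats[season][param]
        return MarginalSpec(param, season, lo, hi, mean, conc=self.beta_conc)


# --- internal transforms -----------------------------------------------------


def _stratified_squeeze(u: np.ndarray, n_upper: int, boundary: float) -> np.ndarray:
    """Piecewise-linear monotone remap of uniforms so that exactly the
    ``n_upper`` largest entries land in (boundary, 1] and the rest in
    [0, boundary).  Global rank order is preserved, so dependence imposed
    through the copula survives the stratification."""
    if n_upper <= 0:
        return u
    if n_upper >= len(u):
        raise ValueError("cannot place every sample in the upper stratum")
    order = np.sort(u)
    c, d = order[-n_upper - 1], order[-n_upper]
    knot = 0.5 * (c + d)
    out = np.empty_like(u)
    low = u <= knot
    out[low] = u[low] * (boundary / knot)
    out[~low] = boundary + (u[~low] - knot) * (1.0 - boundary) / (1.0 - knot)
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def _power_nudge_unit(t: np.ndarray, target_frac: float) -> np.ndarray:
    """Raise unit-interval values to a power so their mean hits target_frac.

    Monotone and bound-preserving; if the target is unreachable the exponent
    is clamped at the search bounds.
    """
    t = np.clip(t, 0.0, 1.0)
    if len(t) == 0 or np.all(t == t[0]):
        return t

    def f(log_g: float) -> float:
        return float(np.mean(t ** np.exp(log_g))) - target_frac

    lo, hi = -7.0, 7.0
    flo, fhi = f(lo), f(hi)
    if flo <= 0:  # even gamma -> 0 cannot raise mean enough; keep as-is
        return t ** np.exp(lo)
    if fhi >= 0:
        return t ** np.exp(hi)
    log_g = optimize.brentq(f, lo, hi, xtol=1e-12)
    return t ** np.exp(log_g)


def _nudge_mean(values: np.ndarray, lo: float, hi: float, target_mean: float) -> np.ndarray:
    """Bounded power-transform of values on [lo, hi] to the target mean."""
    if hi == lo:
        return values
    t = _power_nudge_unit((values - lo) / (hi - lo), (target_mean - lo) / (hi - lo))
    return lo + (hi - lo) * t


def _nudge_mean_stratified(
    values: np.ndarray, lo: float, boundary: float, target_total_mean: float
) -> np.ndarray:
    """Adjust only the below-boundary stratum so the overall mean matches.

    Upper-stratum values (the forced exceedances) stay fixed, so the
    exceedance count is preserved exactly.
    """
    upper = values > boundary
    n = len(values)
    lower_vals = values[~upper]
    if len(lower_vals) == 0:
        return values
    need = (target_total_mean * n - values[upper].sum()) / len(lower_vals)
    need = min(max(need, lo), boundary)
    out = values.copy()
    out[~upper] = _nudge_mean(lower_vals, lo, boundary, need)
    return out


def _squeeze_batch(u: np.ndarray, n_upper: int, boundary: float) -> np.ndarray:
    """Vectorised :func:`_stratified_squeeze` over batches (rows)."""
    if n_upper <= 0:
        return u
    order = np.sort(u, axis=1)
    knot = 0.5 * (order[:, [-n_upper - 1]] + order[:, [-n_upper]])
    low = u <= knot
    out = np.where(
        low,
        u * (boundary / knot),
        boundary + (u - knot) * (1.0 - boundary) / (1.0 - knot),
    )
    return np.clip(out, 1e-12, 1.0 - 1e-12)


@lru_cache(maxsize=64)
def _calibrate_rho(
    spec_x: tuple,
    spec_y: tuple,
    target: float,
    n: int,
    n_upper: int,
    boundary_value: float | None,
) -> float:
    """Gaussian-copula correlation whose transformed sample Pearson r,
    averaged over many size-``n`` surveys, hits the target.

    The calibration simulates the generator's own per-survey transforms
    (rank stratification at the exceedance boundary and the bounded mean
    nudge of the x margin) on a fixed common-random-number ensemble, then
    fixed-point-adjusts rho.  Deterministic and cached, so repeated
    generator calls pay for it once per process.
    """
    if target == 0.0:
        return 0.0
    sx = MarginalSpec(*spec_x)
    mx = fit_marginal(sx)
    my = fit_marginal(MarginalSpec(*spec_y))
    batches = 400
    rng = np.random.default_rng(987654321)
    z1 = rng.standard_normal((batches, n))
    zaux = rng.standard_normal((batches, n))
    p_b = float(mx.cdf(boundary_value)) if boundary_value is not None else 1.0

    def realised(rho: float) -> float:
        z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * zaux
        u1 = stats.norm.cdf(z1)
        if n_upper > 0 and boundary_value is not None:
            u1 = _squeeze_batch(u1, n_upper, p_b)
        x = np.asarray(mx.ppf(u1))
        if n_upper > 0 and boundary_value is not None:
            for b in range(batches):
                x[b] = _nudge_mean_stratified(x[b], sx.min, boundary_value, sx.mean)
        y = np.asarray(my.ppf(stats.norm.cdf(z2)))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        return float(r.mean())

    rho = target
    for _ in range(4):
        r = realised(rho)
        if abs(r) < 1e-9:
            break
        rho = float(np.clip(rho * target / r, -0.999, 0.999))
    return rho


# --- generation --------------------------------------------------------------


def _season_frame(
    cfg: GeneratorConfig, season: str, rng: np.random.Generator
) -> pd.DataFrame:
    n = cfg.n_wells
    wells = list(cfg.wells[:n])
    exc = [w for w in cfg.exceedance_wells.get(season, ()) if w in wells]

    no3_spec = cfg.marginal("NO3", season)
    cl_spec = cfg.marginal("Cl", season)
    tds_spec = cfg.marginal("TDS", season)
    no3 = fit_marginal(no3_spec)

    key = lambda s: (s.name, s.season, s.min, s.max, s.mean, s.conc)
    rho_cl = _calibrate_rho(
        key(no3_spec), key(cl_spec), float(cfg.r_no3_cl[season]), n, len(exc), _NO3_LIMIT
    )
    rho_tds = _calibrate_rho(
        key(no3_spec), key(tds_spec), float(cfg.r_no3_tds[season]), n, len(exc), _NO3_LIMIT
    )
    corr = np.array(
        [
            [1.0, rho_cl, rho_tds],
            [rho_cl, 1.0, rho_cl * rho_tds],
            [rho_tds, rho_cl * rho_tds, 1.0],
        ]
    )
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ L.T
    u = stats.norm.cdf(z)

    u_no3 = _stratified_squeeze(u[:, 0], len(exc), float(no3.cdf(_NO3_LIMIT)))
    no3_v = np.asarray(no3.ppf(u_no3))
    no3_v = _nudge_mean_stratified(no3_v, no3_spec.min, _NO3_LIMIT, no3_spec.mean)

    cl_v = _nudge_mean(
        np.asarray(fit_marginal(cl_spec).ppf(u[:, 1])), cl_spec.min, cl_spec.max, cl_spec.mean
    )
    tds_v = _nudge_mean(
        np.asarray(fit_marginal(tds_spec).ppf(u[:, 2])), tds_spec.min, tds_spec.max, tds_spec.mean
    )

    # assign whole copula rows to wells: the highest-NO3 rows go to the
    # named exceedance wells, everything else keeps draw order
    order = np.argsort(-no3_v)
    top = list(order[: len(exc)])
    rest = [i for i in range(n) if i not in top]
    row_for_well: dict[str, int] = {}
    for w, i in zip(exc, top):
        row_for_well[w] = i
    others = [w for w in wells if w not in row_for_well]
    for w, i in zip(others, rest):
        row_for_well[w] = i

    data: dict[str, np.ndarray] = {}
    perm = np.array([row_for_well[w] for w in wells])
    data["NO3"] = no3_v[perm]
    data["Cl"] = cl_v[perm]
    data["TDS"] = tds_v[perm]

    # independent marginals
    for p in ("pH", "EC", "BOD", "COD", "Ca", "Mg", "Na", "K", "HCO3", "SO4"):
        spec = cfg.marginal(p, season)
        v = np.asarray(fit_marginal(spec).rvs(n, rng))
        data[p] = _nudge_mean(v, spec.min, spec.max, spec.mean)

    # hardness with its season-specific roles
    th_spec = cfg.marginal("TH", season)
    th_sampler = fit_marginal(th_spec)
    if season == "wet":
        th_exc = [w for w in cfg.th_exceedance_wells_wet if w in wells]
        u_th = _stratified_squeeze(rng.random(n), len(th_exc), float(th_sampler.cdf(_TH_LIMIT)))
        th_v = np.asarray(th_sampler.ppf(u_th))
        th_v = _nudge_mean_stratified(th_v, th_spec.min, _TH_LIMIT, th_spec.mean)
        th_order = np.argsort(-th_v)
        th_map: dict[str, int] = {}
        for w, i in zip(th_exc, th_order[: len(th_exc)]):
            th_map[w] = i
        rest_idx = [i for i in range(n) if i not in th_map.values()]
        for w, i in zip((w for w in wells if w not in th_map), rest_idx):
            th_map[w] = i
        data["TH"] = th_v[np.array([th_map[w] for w in wells])]
    else:
        # the soft well is pinned to the printed seasonal minimum; the rest
        # stay above the soft/hard split so exactly one well is soft
        sub = MarginalSpec("TH", season, _TH_SOFT_SPLIT, th_spec.max, max(th_spec.mean, _TH_SOFT_SPLIT), cfg.beta_conc)
        rest_v = np.asarray(fit_marginal(sub).rvs(n - 1, rng))
        need = (th_spec.mean * n - th_spec.min) / (n - 1)
        rest_v = _nudge_mean(rest_v, sub.min, sub.max, min(max(need, sub.min), sub.max))
        th_v = np.empty(n)
        soft_idx = wells.index(cfg.soft_well) if cfg.soft_well in wells else 0
        mask = np.ones(n, dtype=bool)
        mask[soft_idx] = False
        th_v[soft_idx] = th_spec.min
        th_v[mask] = rest_v
        data["TH"] = th_v

    frame = pd.DataFrame({"well_id": wells, "season": season, **data})
    return frame


def generate(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate the full two-season samples table.

    Deterministic for a fixed seed (bit-identical CSV on re-run).  Columns
    match the chem module's reader schema.
    """
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_wells
    wells = list(cfg.wells[:n])

    # static well geometry, shared between seasons: high-nitrate named wells
    # cluster in the north-west (urban) corner of the bounding box
    xmin, ymin, xmax, ymax = cfg.bbox
    urban = set().union(*(cfg.exceedance_wells.get(s, ()) for s in cfg.seasons))
    xs, ys = np.empty(n), np.empty(n)
    for i, w in enumerate(wells):
        if w in urban:
            xs[i] = rng.uniform(xmin + 0.05 * (xmax - xmin), xmin + 0.30 * (xmax - xmin))
            ys[i] = rng.uniform(ymin + 0.70 * (ymax - ymin), ymin + 0.95 * (ymax - ymin))
        else:
            xs[i] = rng.uniform(xmin, xmax)
            ys[i] = rng.uniform(ymin, ymax)
    depth = rng.uniform(*cfg.depth_range, size=n)

    frames = []
    for season in cfg.seasons:
        f = _season_frame(cfg, season, rng)
        f.insert(2, "x", np.round(xs, 2))
        f.insert(3, "y", np.round(ys, 2))
        f.insert(4, "depth_m", np.round(depth, 1))
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    cols = [
        "well_id", "season", "x", "y", "depth_m",
        "pH", "EC", "TDS", "TH", "BOD", "COD",
        "Ca", "Mg", "Na", "K", "HCO3", "Cl", "SO4", "NO3",
    ]
    df = df[cols]
    num = df.columns.difference(["well_id", "season"])
    df[num] = df[num].round(6)
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    """Write the samples table as CSV with a stable column order."""
    df.to_csv(path, index=False)


# --- embedded unit-test fixture ----------------------------------------------

#: Five wells on a charge-balanced meq recipe; NO3 of F-3 is exactly 32 mg/L
#: so that HI = 1 at an effective ingestion rate of 0.05 L/(kg day) with
#: RfD 1.6 mg/kg/day.
_FIXTURE_MEQ = {
    #            Ca    Mg    Na    K     HCO3  Cl    SO4   NO3(meq)
    "F-1": (3.00, 1.50, 1.00, 0.05, 3.50, 1.00, 0.60, 0.45),
    "F-2": (2.40, 1.20, 1.40, 0.04, 3.00, 1.10, 0.50, 0.44),
    "F-3": (3.60, 1.80, 0.80, 0.06, 4.20, 0.90, 0.64, None),  # NO3 fixed in mg/L
    "F-4": (2.00, 1.00, 1.80, 0.03, 2.60, 1.30, 0.43, 0.50),
    "F-5": (4.20, 2.10, 0.60, 0.07, 5.00, 0.80, 0.77, 0.40),
}
_FIXTURE_PH = {"F-1": 7.40, "F-2": 7.20, "F-3": 7.80, "F-4": 7.00, "F-5": 7.60}
_FIXTURE_BOD = {"F-1": 6.0, "F-2": 5.5, "F-3": 7.5, "F-4": 5.0, "F-5": 8.0}
_FIXTURE_COD = {"F-1": 12.0, "F-2": 11.0, "F-3": 15.0, "F-4": 10.0, "F-5": 16.0}


def fixture_small() -> pd.DataFrame:
    """Deterministic 5-well toy table for unit-test oracles.

    Built from a near charge-balanced milliequivalent recipe, converted to
    mg/L through the ion registry; the four EWQI test parameters are pH,
    TH, BOD and NO3.
    """
    from .chem import ION_REGISTRY, total_hardness

    def mg(meq: float, ion: str) -> float:
        spec = ION_REGISTRY[ion]
        return round(meq * spec.molar_mass / spec.valence, 4)

    rows = []
    for i, (well, (ca, mgq, na, k, hco3, cl, so4, no3)) in enumerate(_FIXTURE_MEQ.items()):
        rec = {
            "well_id": well,
            "season": "wet",
            "x": 100.0 * (i + 1),
            "y": 50.0 * (i + 1),
            "pH": _FIXTURE_PH[well],
            "EC": 500.0 + 20.0 * i,
            "TDS": 250.0 + 10.0 * i,
            "BOD": _FIXTURE_BOD[well],
            "COD": _FIXTURE_COD[well],
            "Ca": mg(ca, "Ca"),
            "Mg": mg(mgq, "Mg"),
            "Na": mg(na, "Na"),
            "K": mg(k, "K"),
            "HCO3": mg(hco3, "HCO3"),
            "Cl": mg(cl, "Cl"),
            "SO4": mg(so4, "SO4"),
            "NO3": 32.0 if no3 is None else mg(no3, "NO3"),
        }
        rec["TH"] = round(total_hardness(rec["Ca"], rec["Mg"]), 4)
        rows.append(rec)
    return pd.DataFrame(rows)
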