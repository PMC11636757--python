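"""Entropy-weighted water quality index (EWQI).

The index aggregates per-parameter quality ratings with weights derived from
the Shannon entropy of the observed data matrix: a parameter whose values
vary strongly across samples carries low entropy and hence high weight.

Pipeline: raw matrix X (m samples x n parameters) -> min-max normalised Y ->
column proportion matrix P -> entropies e_j -> weights w_j -> quality
ratings q_j = 100*C_j/S_j against drinking-water limits -> score
EWQI_i = sum_j w_j q_ij -> five quality ranks I (excellent) to V (extremely
poor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import StandardsTable, total_hardness

__all__ = [
    "EwqiMatrix",
    "EwqiResult",
    "normalize",
    "entropy_weights",
    "quality_rating",
    "ewqi_score",
    "classify",
    "run_ewqi",
    "RANK_THRESHOLDS",
    "RANK_LABELS",
]

#: Upper bounds of ranks I-IV; scores >= the last bound are rank V.
RANK_THRESHOLDS: tuple[float, ...] = (25.0, 50.0, 100.0, 150.0)

RANK_LABELS: dict[str, str] = {
    "I": "excellent",
    "II": "good",
    "III": "moderate",  # marginally suitable for drinking
    "IV": "poor",  # not recommended for drinking
    "V": "extremely poor",
}

_RANKS = ("I", "II", "III", "IV", "V")


@dataclass
class EwqiMatrix:
    """Raw and normalised evaluation matrices for one EWQI run."""

    samples: list[str]
    parameters: list[str]
    X: np.ndarray  # m x n raw values
    Y: np.ndarray  # m x n min-max normalised values in [0, 1]
    degenerate: np.ndarray  # length-n bool: column was constant


def normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise min-max normalisation of the evaluation matrix.

    Returns ``(Y, degenerate)`` where degenerate flags constant columns,
    which are set to all zeros (they carry no discriminating information and
    are excluded from weighting downstream).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to normalise")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in evaluation matrix")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    safe = np.where(degenerate, 1.0, span)
    Y = (X - lo) / safe
    Y[:, degenerate] = 0.0
    return Y, degenerate


def entropy_weights(
    Y: np.ndarray, degenerate: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Shannon entropies e_j and entropy weights w_j from the normalised matrix.

    P_ij = y_ij / sum_i y_ij with the convention 0*ln(0) = 0;
    e_j = -(1/ln m) * sum_i P_ij ln P_ij; w_j = (1-e_j) / sum_j (1-e_j).
    Degenerate (constant) columns get e_j = 1 and zero weight.  Raises if
    every column is degenerate (no information to weight).
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    if degenerate is None:
        degenerate = Y.max(axis=0) == Y.min(axis=0)
    e = np.ones(n)
    for j in range(n):
        if degenerate[j]:
            continue
        col = Y[:, j]
        s = col.sum()
        if s == 0:
            degenerate = degenerate.copy()
            degenerate[j] = True
            continue
        p = col / s
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        e[j] = -terms.sum() / np.log(m)
    info = 1.0 - e
    total = info.sum()
    if total <= 0:
        raise ValueError("all parameters degenerate: entropy weights undefined")
    w = info / total
    return e, w


def quality_rating(
    sample: Mapping[str, float],
    standards: StandardsTable,
    parameters: Sequence[str],
) -> np.ndarray:
    """Quality ratings q_j = 100 * C_j / S_j for one sample.

    pH is rated against its permissible band around neutrality:
    q_pH = 100 * (pH - 7) / (S_pH - 7) with S_pH = 8.5 above 7 and 6.5 below
    7, so q is always >= 0 and q = 0 at exactly pH 7.
    """
    q = np.empty(len(parameters))
    for j, p in enumerate(parameters):
        c = float(sample[p])
        if p == "pH":
            if c == 7.0:
                q[j] = 0.0
            else:
                s_ph = standards.ph_band[1] if c > 7.0 else standards.ph_band[0]
                q[j] = 100.0 * (c - 7.0) / (s_ph - 7.0)
        else:
            s = standards.limit(p)
            if s == 0:
                raise ValueError(f"zero standard for {p}")
            q[j] = 100.0 * c / s
    return q


def ewqi_score(w: np.ndarray, q: np.ndarray) -> float:
    """Weighted sum EWQI = sum_j w_j q_j for one sample."""
    w = np.asarray(w, dtype=float)
    q = np.asarray(q, dtype=float)
    if w.shape != q.shape:
        raise ValueError("weight and rating vectors differ in length")
    return float(w @ q)


def classify(
    score: float, thresholds: Sequence[float] = RANK_THRESHOLDS
) -> tuple[str, str]:
    """Map a score to (rank, label): I <25, II [25,50), III [50,100),
    IV [100,150), V >=150 under the default thresholds."""
    if score < 0:
        raise ValueError("EWQI score must be >= 0")
    idx = int(np.searchsorted(np.asarray(thresholds, dtype=float), score, side="right"))
    rank = _RANKS[idx]
    return rank, RANK_LABELS[rank]


@dataclass
class EwqiResult:
    """Entropies, weights, ratings, scores and ranks for one EWQI run."""

    season: str | None
    parameters: list[str]
    samples: list[str]
    entropy: pd.Series  # e_j per parameter
    weights: pd.Series  # w_j per parameter, sums to 1
    ratings: pd.DataFrame  # q_ij, samples x parameters
    scores: pd.Series  # EWQI per sample
    table: pd.DataFrame = field(default_factory=pd.DataFrame)  # well, score, rank

    def to_json_sidecar(self, path: str | Path) -> None:
        import json

        payload = {
            "season": self.season,
            "parameters": self.parameters,
            "entropy": self.entropy.round(12).to_dict(),
            "weights": self.weights.round(12).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_ewqi(
    df: pd.DataFrame,
    parameters: Sequence[str],
    standards: StandardsTable | None = None,
    wells: Sequence[str] | None = None,
    season: str | None = None,
    thresholds: Sequence[float] = RANK_THRESHOLDS,
) -> EwqiResult:
    """Full EWQI pipeline on one season's (sub)set of wells.

    Weights are computed per run from the selected samples only, so each
    season (and each well subset) forms its own evaluation matrix.  TH is
    computed from Ca and Mg where the column is null.
    """
    standards = standards or StandardsTable.who_defaults()
    sub = df
    if season is not None:
        sub = sub[sub["season"] == season]
    if wells is not None:
        sub = sub[sub["well_id"].isin(set(wells))]
        missing = set(wells) - set(sub["well_id"])
        if missing:
            raise ValueError(f"wells not in table: {sorted(missing)}")
    if len(sub) < 2:
        raise ValueError("need at least 2 samples for an EWQI run")
    sub = sub.reset_index(drop=True)

    work = sub.copy()
    if "TH" in parameters:
        th = work["TH"].astype(float) if "TH" in work.columns else pd.Series(np.nan, index=work.index)
        if th.isna().any():
            if not {"Ca", "Mg"}.issubset(work.columns):
                raise ValueError("TH missing and not computable (no Ca/Mg columns)")
            th = pd.Series(
                np.where(pd.isna(th), total_hardness(work["Ca"], work["Mg"]), th),
                index=work.index,
            )
        work["TH"] = th
    missing_cols = [p for p in parameters if p not in work.columns]
    if missing_cols:
        raise ValueError(f"parameters not in table: {missing_cols}")

    X = work[list(parameters)].to_numpy(dtype=float)
    Y, degenerate = normalize(X)
    e, w = entropy_weights(Y, degenerate)
    q = np.vstack([quality_rating(rec, standards, parameters) for _, rec in work.iterrows()])
    scores = q @ w

    samples = list(work["well_id"].astype(str))
    ranks = [classify(s, thresholds) for s in scores]
    table = pd.DataFrame(
        {
            "well_id": samples,
            "season": work["season"] if "season" in work.columns else season,
            "EWQI": np.round(scores, 2),
            "rank": [r for r, _ in ranks],
            "label": [lbl for _, lbl in ranks],
        }
    )
    return EwqiResult(
        season=season,
        parameters=list(parameters),
        samples=samples,
        entropy=pd.Series(e, index=list(parameters), name="entropy"),
        weights=pd.Series(w, index=list(parameters), name="weight"),
        ratings=pd.DataFrame(q, index=samples, columns=list(parameters)),
        scores=pd.Series(scores, index=samples, name="EWQI"),
        table=table,
    )
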