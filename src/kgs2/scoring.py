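"""Reference-anchored score adjustment.

A base scoring function SF relates to experimental affinity through a
linear calibration, pred = b + k * score. Given a reference complex R
with known experimental affinity R_exp and raw score R_score, the
adjusted affinity of a query Q is

    Q_hat = R_exp + k * (Q_score - R_score)

so that systematic errors shared by two similar complexes cancel. When
no qualified reference is found the plain calibration line
Q_hat = b + k * Q_score is used instead (flagged as a fallback).

All affinities are binding constants in logarithmic units (logKa:
-logKd / -logKi / -logIC50, treated interchangeably). The slope k is
per scoring function and is calibrated from data, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from kgs2.structures import ComplexRecord
from kgs2.fingerprints import Fingerprint, build_fingerprint
from kgs2.patterns import PatternLibrary
from kgs2.similarity import MIN_SI, search_reference

__all__ = [
    "ScoreTable",
    "CalibrationResult",
    "AdjustedScore",
    "calibrate",
    "adjust_score",
    "score_query",
    "abs_error",
    "evaluate_set",
    "rerank_poses",
]


@dataclass
class ScoreTable:
    """Raw scoring-function output, optionally with experimental data.

    Backed by a DataFrame with columns ``complex_id``, ``raw_score`` and
    (optional) ``experimental`` in logKa units.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("complex_id", "raw_score"):
            if col not in df.columns:
                raise ValueError(f"score table missing column {col!r}")
        if "experimental" not in df.columns:
            df = df.assign(experimental=np.nan)
        df = df.copy()
        df["complex_id"] = df["complex_id"].astype(str)
        if df["complex_id"].duplicated().any():
            dup = df.loc[df["complex_id"].duplicated(), "complex_id"].iloc[0]
            raise ValueError(f"duplicate id {dup!r} in score table")
        if not np.all(np.isfinite(df["raw_score"].to_numpy(float))):
            raise ValueError("non-finite raw scores in score table")
        self.frame = df.reset_index(drop=True)
        self._scores = dict(zip(df["complex_id"], df["raw_score"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t", comment="#",
                               dtype={"complex_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def raw_score(self, complex_id: str) -> float:
        try:
            return float(self._scores[str(complex_id)])
        except KeyError:
            raise KeyError(
                f"no raw score for complex {complex_id!r}") from None

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CalibrationResult:
    """Linear calibration of a scoring function against experiment."""

    k: float  # slope, logKa per score unit
    b: float  # intercept, logKa
    r: float  # Pearson correlation
    sd: float  # residual standard deviation of the fit, logKa
    n: int

    def predict(self, raw_score: float) -> float:
        return self.b + self.k * raw_score


@dataclass
class AdjustedScore:
    query_id: str
    reference_id: Optional[str]
    q_raw: float
    r_raw: Optional[float]
    r_exp: Optional[float]
    adjusted: float
    si_used: Optional[float]
    fallback: bool


def calibrate(table: ScoreTable) -> CalibrationResult:
    """Ordinary least squares of experimental affinity on raw score.

    The slope is the k parameter of the score adjustment; sd is the
    residual standard deviation (n - 2 denominator), the "standard
    deviation in regression" reported for scoring-function benchmarks.
    """
    df = table.frame.dropna(subset=["experimental"])
    n = len(df)
    if n < 3:
        raise ValueError(f"calibration needs >= 3 scored complexes, got {n}")
    x = df["raw_score"].to_numpy(float)
    y = df["experimental"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("raw scores have zero variance; slope undefined")
    fit = sps.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    sd = float(np.sqrt(np.sum(residuals ** 2) / (n - 2))) if n > 2 else 0.0
    return CalibrationResult(k=float(fit.slope), b=float(fit.intercept),
                             r=float(fit.rvalue), sd=sd, n=n)


def adjust_score(q_raw: float, r_raw: float, r_exp: float, k: float) -> float:
    """Reference-anchored adjusted affinity:
    adjusted = r_exp + k * (q_raw - r_raw)."""
    for v in (q_raw, r_raw, r_exp, k):
        if not np.isfinite(v):
            raise ValueError("adjust_score requires finite inputs")
    return r_exp + k * (q_raw - r_raw)


def abs_error(experimental: float, predicted: float) -> float:
    """Absolute prediction error in logKa units."""
    if not (np.isfinite(experimental) and np.isfinite(predicted)):
        raise ValueError("abs_error requires finite inputs")
    return abs(experimental - predicted)


def score_query(
    query: ComplexRecord,
    base_score: float,
    pattern_library: PatternLibrary,
    reference_fps: Sequence[Fingerprint],
    reference_scores: ScoreTable,
    calibration: CalibrationResult,
    min_si: float = MIN_SI,
    mode: str = "full",
    exclude_ids: Iterable[str] = (),
    query_fp: Optional[Fingerprint] = None,
) -> AdjustedScore:
    """Score one query complex.

    The query is fingerprinted, the reference library searched, and the
    adjusted score computed against the best qualified reference; with
    no reference the calibration line is applied and the result flagged
    as a fallback. A reference lacking a raw score is an error: the
    adjustment cannot be evaluated without it.
    """
    if query_fp is None:
        query_fp = build_fingerprint(query, pattern_library, mode=mode)
    ref, result = search_reference(
        query_fp, reference_fps, min_si=min_si,
        exclude_ids=exclude_ids,
        mode=mode if mode == "protein_only" else None)
    if ref is None:
        return AdjustedScore(
            query_id=query.complex_id, reference_id=None,
            q_raw=base_score, r_raw=None, r_exp=None,
            adjusted=calibration.predict(base_score),
            si_used=None, fallback=True)
    if ref.affinity is None or not np.isfinite(ref.affinity):
        raise ValueError(
            f"reference {ref.complex_id} has no experimental affinity")
    r_raw = reference_scores.raw_score(ref.complex_id)
    return AdjustedScore(
        query_id=query.complex_id, reference_id=ref.complex_id,
        q_raw=base_score, r_raw=r_raw, r_exp=ref.affinity,
        adjusted=adjust_score(base_score, r_raw, ref.affinity, calibration.k),
        si_used=result.si, fallback=False)


def evaluate_set(
    predictions: Sequence[float], experimentals: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson correlation and regression SD of a prediction set.

    SD is the residual standard deviation of the linear fit of
    experimental on predicted values (n - 2 denominator). Returns
    (r_p, sd, n).
    """
    pred = np.asarray(predictions, float)
    exp = np.asarray(experimentals, float)
    if pred.shape != exp.shape:
        raise ValueError("prediction/experimental length mismatch")
    n = pred.size
    if n < 3:
        raise ValueError("evaluation needs >= 3 samples")
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        raise ValueError("zero variance; correlation undefined")
    fit = sps.linregress(pred, exp)
    residuals = exp - (fit.intercept + fit.slope * pred)
    sd = float(np.sqrt(np.sum(residuals ** 2) / (n - 2)))
    return float(fit.rvalue), sd, n


def rerank_poses(
    poses: Sequence[tuple[ComplexRecord, float]],
    pattern_library: PatternLibrary,
    reference_fps: Sequence[Fingerprint],
    reference_scores: ScoreTable,
    calibration: CalibrationResult,
    min_si: float = MIN_SI,
    mode: str = "full",
    exclude_ids: Iterable[str] = (),
) -> tuple[pd.DataFrame, AdjustedScore]:
    """Re-rank docking poses of one ligand by adjusted score.

    ``poses`` is a sequence of (ComplexRecord, raw_score); each pose is
    independently fingerprinted, referenced and adjusted, then the poses
    are sorted by adjusted score (descending, i.e. best predicted
    affinity first). Returns the ranked table and the top pose's
    adjusted score, which is the ligand's predicted affinity.
    """
    if not poses:
        raise ValueError("no poses to rank")
    adjusted: list[AdjustedScore] = []
    for record, raw in poses:
        adjusted.append(score_query(
            record, raw, pattern_library, reference_fps, reference_scores,
            calibration, min_si=min_si, mode=mode, exclude_ids=exclude_ids))
    order = sorted(range(len(adjusted)),
                   key=lambda i: (-adjusted[i].adjusted, adjusted[i].query_id))
    table = pd.DataFrame([
        {
            "pose_id": adjusted[i].query_id,
            "raw_score": adjusted[i].q_raw,
            "adjusted": adjusted[i].adjusted,
            "reference_id": adjusted[i].reference_id,
            "si": adjusted[i].si_used,
            "fallback": adjusted[i].fallback,
            "rank": rank + 1,
        }
        for rank, i in enumerate(order)
    ])
    return table, adjusted[order[0]]
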