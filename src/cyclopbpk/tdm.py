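"""Agreement statistics between predicted and observed trough levels.

Implements the deviation statistics used for therapeutic-drug-monitoring
evaluation of the model: signed absolute deviation, base-10 log residuum
R = log10(C0_pred/C0_obs), bias B = mean(C_obs − C_pred), precision
P = RMS(C_obs − C_pred), mean relative deviation MRD = 10^RMS(log10 error),
mean percentage error MPE, fold-agreement fractions (|R| < log10(k)) and
stratification of residua by body-weight-normalized dose or by patient.

All RMS/variance quantities use the population (divide-by-n) form, matching
the defining formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TroughObservation",
    "MatchedPair",
    "PerformanceStats",
    "absolute_deviation",
    "residuum",
    "bias",
    "precision",
    "mrd",
    "mpe",
    "fold_agreement",
    "stratify",
    "summarize",
    "match_pairs",
    "TroughAgreement",
    "TroughAgreementResults",
]

TWOFOLD_BAND = np.log10(2.0)    # 0.3010…, printed as 0.30
THREEFOLD_BAND = np.log10(3.0)  # 0.4771…, printed as 0.48


@dataclass(frozen=True)
class TroughObservation:
    patient_id: str
    dose_mg: float
    c0_obs_ng_ml: float

    def __post_init__(self):
        if self.dose_mg <= 0 or self.c0_obs_ng_ml <= 0:
            raise ValueError("dose and observed trough must be positive")


@dataclass(frozen=True)
class MatchedPair:
    patient_id: str
    dose_mg: float
    bw_dose_mg_kg: float
    c0_pred: float
    c0_obs: float

    def __post_init__(self):
        if self.c0_pred <= 0 or self.c0_obs <= 0:
            raise ValueError("concentrations must be positive for ratio statistics")


@dataclass(frozen=True)
class PerformanceStats:
    bias_ng_ml: float
    precision_ng_ml: float
    mrd: float
    mpe_percent: float
    median_abs_dev_ng_ml: float
    abs_dev_iqr_ng_ml: tuple
    frac_within_2fold: float
    frac_within_3fold: float
    n: int


def _arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray([p.c0_pred for p in pairs], dtype=float)
    obs = np.asarray([p.c0_obs for p in pairs], dtype=float)
    if pred.size == 0:
        raise ValueError("no matched pairs")
    return pred, obs


def absolute_deviation(pair: MatchedPair) -> float:
    """Signed deviation C0_pred − C0_obs (ng/ml)."""
    return pair.c0_pred - pair.c0_obs


def residuum(c0_pred: float, c0_obs: float) -> float:
    """R = log10(C0_pred / C0_obs)."""
    if c0_pred <= 0 or c0_obs <= 0:
        raise ValueError("residuum requires positive concentrations")
    return float(np.log10(c0_pred / c0_obs))


def bias(pairs) -> float:
    """B = mean(C_obs − C_pred), ng/ml."""
    pred, obs = _arrays(pairs)
    return float(np.mean(obs - pred))


def precision(pairs) -> float:
    """P = sqrt(mean((C_obs − C_pred)^2)), ng/ml (population form)."""
    pred, obs = _arrays(pairs)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mrd(pairs) -> float:
    """MRD = 10 ** sqrt(mean((log10 C_obs − log10 C_pred)^2))."""
    pred, obs = _arrays(pairs)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("MRD requires positive concentrations")
    x = np.sqrt(np.mean((np.log10(obs) - np.log10(pred)) ** 2))
    return float(10.0 ** x)


def mpe(pairs) -> float:
    """MPE = mean((C_pred − C_obs)/C_obs) · 100, percent."""
    pred, obs = _arrays(pairs)
    if np.any(obs <= 0):
        raise ValueError("MPE requires positive observed concentrations")
    return float(np.mean((pred - obs) / obs * 100.0))


def fold_agreement(pairs, k: float) -> float:
    """Fraction of pairs whose prediction/observation ratio lies strictly within k-fold."""
    if k <= 1:
        raise ValueError("fold threshold must exceed 1")
    pred, obs = _arrays(pairs)
    r = np.abs(np.log10(pred / obs))
    return float(np.mean(r < np.log10(k)))


def stratify(pairs, by: str, bw_dose_bin_width: float = 0.25) -> pd.DataFrame:
    """Residua grouped by body-weight-normalized dose bin or by patient.

    Returns one row per group with the residuum list, its median and n,
    ordered by stratum.
    """
    if by not in ("bw_dose_bin", "patient_id"):
        raise ValueError("stratify by 'bw_dose_bin' or 'patient_id'")
    df = pd.DataFrame({
        "patient_id": [p.patient_id for p in pairs],
        "bw_dose": [p.bw_dose_mg_kg for p in pairs],
        "residuum": [residuum(p.c0_pred, p.c0_obs) for p in pairs],
    })
    if by == "bw_dose_bin":
        df["stratum"] = (np.floor(df["bw_dose"] / bw_dose_bin_width) * bw_dose_bin_width).round(6)
    else:
        df["stratum"] = df["patient_id"]
    grouped = (
        df.groupby("stratum")["residuum"]
        .agg(residua=list, median_residuum="median", n="count")
        .reset_index()
        .sort_values("stratum", kind="stable")
        .reset_index(drop=True)
    )
    return grouped


def summarize(pairs) -> PerformanceStats:
    """All agreement statistics plus the median absolute deviation and its IQR."""
    pred, obs = _arrays(pairs)
    dev = pred - obs
    q25, q75 = np.percentile(dev, [25, 75])
    return PerformanceStats(
        bias_ng_ml=bias(pairs),
        precision_ng_ml=precision(pairs),
        mrd=mrd(pairs),
        mpe_percent=mpe(pairs),
        median_abs_dev_ng_ml=float(np.median(dev)),
        abs_dev_iqr_ng_ml=(float(q25), float(q75)),
        frac_within_2fold=fold_agreement(pairs, 2.0),
        frac_within_3fold=fold_agreement(pairs, 3.0),
        n=len(pred),
    )


def match_pairs(predictions: pd.DataFrame, observations: pd.DataFrame,
                patients: pd.DataFrame | None = None) -> tuple[list, int]:
    """Join predictions and observations on (patient_id, dose_mg).

    ``predictions`` needs columns patient_id, dose_mg, c0_pred; ``observations``
    patient_id, dose_mg, c0_obs.  Body-weight-normalized dose uses ``patients``
    (patient_id, body_weight_kg) when given, else NaN.  Returns (pairs,
    n_dropped) where rows lacking a counterpart or a positive value are dropped.
    """
    pred = predictions.copy()
    obs = observations.copy()
    pred["patient_id"] = pred["patient_id"].astype(str)
    obs["patient_id"] = obs["patient_id"].astype(str)
    merged = obs.merge(pred, on=["patient_id", "dose_mg"], how="left")
    if patients is not None:
        pts = patients.copy()
        pts["patient_id"] = pts["patient_id"].astype(str)
        merged = merged.merge(pts[["patient_id", "body_weight_kg"]], on="patient_id", how="left")
    else:
        merged["body_weight_kg"] = np.nan
    ok = merged["c0_pred"].notna() & (merged["c0_pred"] > 0) & (merged["c0_obs"] > 0)
    pairs = [
        MatchedPair(patient_id=row.patient_id, dose_mg=float(row.dose_mg),
                    bw_dose_mg_kg=float(row.dose_mg / row.body_weight_kg)
                    if np.isfinite(row.body_weight_kg) else float("nan"),
                    c0_pred=float(row.c0_pred), c0_obs=float(row.c0_obs))
        for row in merged[ok].itertuples()
    ]
    return pairs, int((~ok).sum())


@dataclass
class TroughAgreement:
    """Agreement analysis of matched predicted/observed trough pairs.

    Statsmodels-style: construct from pairs (or frames via
    :meth:`from_frames`), call :meth:`fit` for a results object.
    """

    pairs: list
    n_dropped: int = 0

    @classmethod
    def from_frames(cls, predictions: pd.DataFrame, observations: pd.DataFrame,
                    patients: pd.DataFrame | None = None) -> "TroughAgreement":
        pairs, dropped = match_pairs(predictions, observations, patients)
        return cls(pairs=pairs, n_dropped=dropped)

    def fit(self) -> "TroughAgreementResults":
        return TroughAgreementResults(pairs=self.pairs, stats=summarize(self.pairs),
                                      n_dropped=self.n_dropped)


@dataclass
class TroughAgreementResults:
    pairs: list
    stats: PerformanceStats
    n_dropped: int = 0
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame({
                "patient_id": [p.patient_id for p in self.pairs],
                "dose_mg": [p.dose_mg for p in self.pairs],
                "bw_dose_mg_kg": [p.bw_dose_mg_kg for p in self.pairs],
                "c0_pred": [p.c0_pred for p in self.pairs],
                "c0_obs": [p.c0_obs for p in self.pairs],
                "abs_deviation": [absolute_deviation(p) for p in self.pairs],
                "residuum": [residuum(p.c0_pred, p.c0_obs) for p in self.pairs],
            })
        return self._frame

    def stratify(self, by: str, bw_dose_bin_width: float = 0.25) -> pd.DataFrame:
        return stratify(self.pairs, by=by, bw_dose_bin_width=bw_dose_bin_width)

    def summary(self) -> str:
        s = self.stats
        return "\n".join([
            "Trough prediction agreement",
            f"  n pairs: {s.n} (dropped: {self.n_dropped})",
            f"  bias B (obs - pred): {s.bias_ng_ml:.1f} ng/ml",
            f"  precision P (RMS):   {s.precision_ng_ml:.1f} ng/ml",
            f"  MRD: {s.mrd:.2f}",
            f"  MPE: {s.mpe_percent:.1f} %",
            f"  median deviation (pred - obs): {s.median_abs_dev_ng_ml:.1f} ng/ml "
            f"(IQR {s.abs_dev_iqr_ng_ml[0]:.1f} to {s.abs_dev_iqr_ng_ml[1]:.1f})",
            f"  within twofold: {100 * s.frac_within_2fold:.0f} %",
            f"  within threefold: {100 * s.frac_within_3fold:.0f} %",
        ])
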