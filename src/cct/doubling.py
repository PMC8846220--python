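"""Doubling-time prediction from the length of the cell cycle trajectory.

Rapidly dividing cells have no time to fully degrade mitotic transcripts
during G1, which contracts the cell cycle trajectory; the total length LP of a
principal circle fitted in the plane of (max-scaled) S and G2/M phase scores
is therefore a proxy for cycle duration, and doubling time regresses linearly
on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .principal_curve import fit_principal_curve

__all__ = ["CircleLengthRecord", "RegressionReport", "principal_circle_length",
           "regress_doubling_time"]

MIN_CELLS = 50
RECOMMENDED_CELLS = 300


@dataclass(frozen=True)
class CircleLengthRecord:
    """Per-dataset principal-circle length and (optional) doubling time in hours."""

    dataset_id: str
    lp: float
    n_cells: int
    dt: float | None = None

    def __post_init__(self):
        if self.lp <= 0:
            raise ValueError("LP must be > 0")
        if self.n_cells < RECOMMENDED_CELLS:
            import warnings

            warnings.warn(
                f"{self.dataset_id}: {self.n_cells} cells is below the recommended "
                f"{RECOMMENDED_CELLS}",
                RuntimeWarning,
                stacklevel=2,
            )


def principal_circle_length(
    s_scores: np.ndarray,
    m_scores: np.ndarray,
    q: int = 30,
    stretch: float = 0.005,
    bend: float = 0.05,
):
    """Length LP of the closed principal curve in the max-scaled score plane.

    Each score is divided by its maximum so both axes end at 1; a closed
    elastic curve with ``q`` nodes is fitted and LP is the sum of its edge
    lengths.  Returns ``(lp, curve)``.
    """
    s = np.asarray(s_scores, dtype=float)
    m = np.asarray(m_scores, dtype=float)
    if s.shape != m.shape or s.ndim != 1:
        raise ValueError("scores must be two equal-length 1-D arrays")
    if s.size < MIN_CELLS:
        raise ValueError(f"need at least {MIN_CELLS} cells")
    if np.ptp(s) == 0 or np.ptp(m) == 0:
        raise ValueError("constant scores cannot define a trajectory")
    if s.max() <= 0 or m.max() <= 0:
        raise ValueError("score maxima must be positive for max-scaling")
    pts = np.column_stack([s / s.max(), m / m.max()])
    curve = fit_principal_curve(pts, q=q, closed=True, stretch=stretch, bend=bend)
    return curve.length(), curve


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    predictions: pd.DataFrame  # dataset_id, lp, dt, predicted_dt, excluded
    excluded: list[str]


def regress_doubling_time(
    records: list[CircleLengthRecord],
    outlier_ids: list[str] | None = None,
    auto_outliers: bool = False,
    studentized_threshold: float = 3.0,
) -> RegressionReport:
    """OLS of doubling time on principal-circle length, with explicit outliers.

    ``outlier_ids`` are excluded from the fit (the predictions table still
    covers them); with ``auto_outliers`` records whose externally studentized
    residual exceeds the threshold are additionally flagged and the model is
    refitted without them.  Requires at least 3 usable records with a
    doubling time.
    """
    import statsmodels.api as sm

    outlier_ids = list(outlier_ids or [])
    rows = [(r.dataset_id, r.lp, r.dt) for r in records]
    df = pd.DataFrame(rows, columns=["dataset_id", "lp", "dt"])

    def _fit(excluded: list[str]):
        use = df[df.dt.notna() & ~df.dataset_id.isin(excluded)]
        if len(use) < 3:
            raise ValueError(f"need at least 3 non-excluded records with DT, got {len(use)}")
        X = sm.add_constant(use.lp.to_numpy())
        model = sm.OLS(use.dt.to_numpy(), X).fit()
        return use, model

    use, model = _fit(outlier_ids)
    if auto_outliers:
        student = model.get_influence().resid_studentized_external
        flagged = use.dataset_id.to_numpy()[np.abs(student) > studentized_threshold]
        if len(flagged):
            outlier_ids = outlier_ids + [str(f) for f in flagged]
            use, model = _fit(outlier_ids)

    from scipy.stats import pearsonr

    r, p = pearsonr(use.lp, use.dt)
    intercept, slope = model.params
    preds = df.copy()
    preds["predicted_dt"] = intercept + slope * preds.lp
    preds["excluded"] = preds.dataset_id.isin(outlier_ids)
    return RegressionReport(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=float(r),
        p_value=float(p),
        predictions=preds,
        excluded=outlier_ids,
    )
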