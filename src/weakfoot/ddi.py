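"""Distribution Difference Index (DDI) and the adaptive RWF threshold.

For one subject, let ``v_1..v_N`` be the z-scored weak-foot feature vectors
of the windows at one window length L.  The full-connection distance

    d_L = (1 / (N (N - 1))) * sum_{i != j} ||v_i - v_j||

is the mean Euclidean distance over all ordered pairs.  The DDI is the
ratio ``d_l / d_h`` of that dispersion at a short window length (default
20 steps) to the dispersion at a long length used as a per-subject
baseline; intermittent ("recessive") expression of the high-risk gait
inflates the short-window dispersion much more than the long-window one,
so RWF subjects sit in the high-DDI tail.

The adaptive threshold ``T = DDI_min + (DDI_max - DDI_min) * alpha`` with a
trainable ``alpha`` in [0, 1] flags a subject as RWF iff DDI > T (strict).
Optionally the raw extremes are replaced by the outlier bounds mu +/- 3
sigma, clipped to the observed range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .io import (
    DegenerateGaitError,
    DegenerateCohortWarning,
    InsufficientSamplesError,
    SchemaError,
    ValidationError,
    warn,
)

RWF = "RWF"
DWF = "DWF"


# ---------------------------------------------------------------------------
# Distances and the index
# ---------------------------------------------------------------------------

def full_connection_distance(vs: Sequence[np.ndarray] | np.ndarray) -> float:
    """Mean Euclidean distance over all ordered pairs of feature vectors."""
    arr = np.asarray(vs, dtype=float)
    if arr.ndim != 2:
        raise SchemaError("feature vectors must share one dimension")
    n = arr.shape[0]
    if n < 2:
        raise InsufficientSamplesError("need at least two feature vectors")
    # pdist covers each unordered pair once; the ordered-pair mean is equal
    return float(2.0 * pdist(arr).sum() / (n * (n - 1)))


@dataclass(frozen=True)
class DDIRecord:
    """Per-subject dispersion summary: d_l, d_h and their ratio."""

    subject_id: str
    d_l: float
    d_h: float
    n_low: int
    n_high: int

    def __post_init__(self):
        if self.d_l < 0 or self.d_h < 0:
            raise ValidationError("distances must be non-negative")
        if self.n_low < 2 or self.n_high < 2:
            raise InsufficientSamplesError("DDI needs >= 2 windows at each length")

    @property
    def ddi(self) -> float:
        if self.d_h == 0:
            raise DegenerateGaitError(
                f"{self.subject_id}: all long windows identical (d_h = 0)"
            )
        return self.d_l / self.d_h


def compute_ddi(subject_id: str,
                vs_low: Sequence[np.ndarray] | np.ndarray,
                vs_high: Sequence[np.ndarray] | np.ndarray) -> DDIRecord:
    """DDI from the (already standardised) weak vectors at the two lengths."""
    return DDIRecord(
        subject_id=subject_id,
        d_l=full_connection_distance(vs_low),
        d_h=full_connection_distance(vs_high),
        n_low=len(vs_low),
        n_high=len(vs_high),
    )


# ---------------------------------------------------------------------------
# Adaptive threshold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdModel:
    """T = ddi_min + (ddi_max - ddi_min) * alpha over the training cohort."""

    alpha: float
    ddi_min: float
    ddi_max: float
    mu: float
    sigma: float
    robust: bool

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must lie in [0, 1]")
        if self.ddi_min > self.ddi_max:
            raise ValidationError("ddi_min must not exceed ddi_max")

    @property
    def T(self) -> float:
        return self.ddi_min + (self.ddi_max - self.ddi_min) * self.alpha


def fit_threshold(train: Sequence[DDIRecord] | Sequence[float], alpha: float,
                  robust: bool = False) -> ThresholdModel:
    """Fit the threshold bounds on training DDI values.

    ``robust`` replaces the raw extremes with mu +/- 3 sigma, clipped to the
    observed range so alpha keeps its [0, 1] meaning.
    """
    vals = np.array([r.ddi if isinstance(r, DDIRecord) else float(r) for r in train])
    if vals.size < 2:
        raise InsufficientSamplesError("threshold fitting needs >= 2 training subjects")
    lo, hi = float(vals.min()), float(vals.max())
    mu, sigma = float(vals.mean()), float(vals.std())
    if robust:
        lo = max(lo, mu - 3.0 * sigma)
        hi = min(hi, mu + 3.0 * sigma)
    if lo == hi:
        warn(DegenerateCohortWarning,
             f"all training DDI values equal ({lo:g}); threshold collapses")
    return ThresholdModel(alpha=float(alpha), ddi_min=lo, ddi_max=hi,
                          mu=mu, sigma=sigma, robust=robust)


def classify_type(ddi: DDIRecord | float, model: ThresholdModel) -> str:
    """RWF iff DDI > T (strictly greater), else DWF."""
    value = ddi.ddi if isinstance(ddi, DDIRecord) else float(ddi)
    return RWF if value > model.T else DWF


def train_threshold_screening(train: Sequence[DDIRecord | float],
                              is_rwf: Sequence[bool],
                              alphas: Sequence[float],
                              robust: bool = False) -> tuple[ThresholdModel, float]:
    """Pick alpha on a labelled cohort by balanced RWF-screening accuracy.

    Mirrors the feasibility analysis in which flagged subjects are compared
    against a known grouping.  Ties go to the smallest alpha.  Returns the
    fitted model and its balanced accuracy.
    """
    truth = np.asarray(is_rwf, dtype=bool)
    if truth.all() or not truth.any():
        raise ValidationError("screening training needs both RWF and DWF subjects")
    best: tuple[ThresholdModel, float] | None = None
    for alpha in alphas:
        model = fit_threshold(train, alpha, robust=robust)
        pred = np.array([classify_type(r, model) == RWF for r in train])
        tpr = float(np.mean(pred[truth]))
        tnr = float(np.mean(~pred[~truth]))
        bal = 0.5 * (tpr + tnr)
        if best is None or bal > best[1] + 1e-12:
            best = (model, bal)
    assert best is not None
    return best
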