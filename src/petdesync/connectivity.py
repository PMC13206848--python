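"""Molecular connectivity: interregional correlation and bootstrap pair fits.

"Connectivity" here is cross-sectional: the Pearson correlation of two
regions' SUVR values *across subjects* of a cohort (interregional
correlation coefficient, ICC — not intraclass correlation).  The matrix gets
a Fisher r-to-z twin for approximately normal inference scales.

For subject-level scoring (next module), every unordered VOI pair of the
*control* cohort receives an ensemble of ordinary-least-squares line fits on
bootstrap resamples (subjects drawn with replacement), summarized by a
consensus fit.  The lower-index VOI in atlas order is always the predictor;
the perpendicular-distance score downstream is insensitive to this
orientation up to the line parameterization, and the rule is recorded in the
ensemble metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import to_wide

__all__ = [
    "ConnectivityMatrix",
    "fisher_z",
    "compute_icc_matrix",
    "PairFitEnsemble",
    "bootstrap_pair_fits",
]

_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher r-to-z: z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    Values with |r| >= 1 (exact collinearity) are clipped to magnitude
    1 - 1e-7 with a warning; NaN input is rejected.
    """
    arr = np.asarray(r, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN correlation passed to fisher_z")
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(arr) >= _CLIP):
        warnings.warn("correlation magnitude >= 1 clipped before atanh",
                      RuntimeWarning, stacklevel=2)
    out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(out) if np.isscalar(r) else out


@dataclass
class ConnectivityMatrix:
    """VOI x VOI Pearson matrix with its Fisher-z twin.

    ``z`` is NaN on the diagonal (atanh(1) undefined by construction).
    """

    vois: tuple[str, ...]
    r: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    @property
    def z(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            z = np.arctanh(np.clip(self.r, -_CLIP, _CLIP))
        np.fill_diagonal(z, np.nan)
        return z

    def to_frame(self, which: str = "r") -> pd.DataFrame:
        m = self.r if which == "r" else self.z
        return pd.DataFrame(m, index=list(self.vois), columns=list(self.vois))


def compute_icc_matrix(table: pd.DataFrame, subjects, vois,
                       tracer: str = "TSPO",
                       age_months: float | None = None) -> ConnectivityMatrix:
    """Interregional Pearson correlation across a cohort's subjects.

    Subjects missing any VOI are dropped listwise (complete profiles only);
    at least 3 complete subjects and nonzero per-VOI variance are required.
    """
    vois = list(vois)
    wide = to_wide(table, tracer=tracer, age_months=age_months, vois=vois)
    wide = wide.loc[wide.index.isin(set(subjects))].dropna(axis=0, how="any")
    if len(wide) < 3:
        raise ValueError(
            f"need >=3 subjects with complete VOI profiles, got {len(wide)}")
    x = wide.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    dead = [v for v, s in zip(vois, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance VOIs: {dead}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(vois=tuple(vois), r=r, n_subjects=len(wide))


@dataclass
class PairFitEnsemble:
    """Bootstrap OLS line fits for every unordered VOI pair of a control cohort.

    ``slopes``/``intercepts`` have shape (B, P) with pairs enumerated in
    ``pairs`` (atlas order, i < j; VOI i is the predictor).  The consensus
    fit is the replicate mean (or median, per ``consensus`` flag at fit
    time).
    """

    vois: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    slopes: np.ndarray
    intercepts: np.ndarray
    consensus_slope: np.ndarray
    consensus_intercept: np.ndarray
    n_control: int
    B: int
    seed: int
    consensus: str = "mean"
    orientation: str = "lower-atlas-index predicts higher"
    control_subjects: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def metadata(self) -> dict:
        return {"n_control": self.n_control, "B": self.B, "seed": self.seed,
                "consensus": self.consensus, "orientation": self.orientation,
                "vois": list(self.vois),
                "control_subjects": list(self.control_subjects)}


def _pair_fits_from_samples(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-replicate OLS for all pairs.

    ``x``: (B, n, V) resampled data.  Returns (slopes, intercepts) of shape
    (B, P) plus the per-replicate predictor variances (B, V) for degeneracy
    checks.  slope(i->j) = cov(i,j)/var(i); intercept = mean_j - slope*mean_i.
    """
    B, n, V = x.shape
    mu = x.mean(axis=1)                        # (B, V)
    xc = x - mu[:, None, :]
    cov = np.einsum("bni,bnj->bij", xc, xc) / (n - 1)
    var = np.einsum("bii->bi", cov).copy()
    iu, ju = np.triu_indices(V, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = cov[:, iu, ju] / var[:, iu]
    intercepts = mu[:, ju] - slopes * mu[:, iu]
    return slopes, intercepts, var


def bootstrap_pair_fits(table: pd.DataFrame, control_subjects, vois,
                        B: int = 1000, seed: int = 0,
                        tracer: str = "TSPO", age_months: float | None = None,
                        consensus: str = "mean",
                        max_redraws: int = 100) -> PairFitEnsemble:
    """Fit B bootstrap OLS lines per VOI pair on the control cohort.

    Each replicate resamples the n control subjects with replacement and
    fits all pairs on the same resample.  Replicates in which any VOI has
    zero variance (so some slope is undefined) are redrawn, up to
    ``max_redraws`` rounds; if the control data are degenerate (a VOI
    constant in the full sample) this raises instead.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if consensus not in ("mean", "median"):
        raise ValueError("consensus must be 'mean' or 'median'")
    vois = list(vois)
    wide = to_wide(table, tracer=tracer, age_months=age_months, vois=vois)
    wide = wide.loc[wide.index.isin(set(control_subjects))].dropna(axis=0, how="any")
    n = len(wide)
    if n < 3:
        raise ValueError(f"need >=3 complete control subjects, got {n}")
    data = wide.to_numpy(dtype=float)
    if np.any(data.std(axis=0) == 0):
        dead = [v for v, s in zip(vois, data.std(axis=0)) if s == 0]
        raise ValueError(f"control VOIs with identical values: {dead}")
    V = len(vois)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424_243]))

    idx = rng.integers(0, n, size=(B, n))
    slopes, intercepts, var = _pair_fits_from_samples(data[idx])
    bad = np.any(var == 0, axis=1)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_redraws:
            raise RuntimeError("degenerate bootstrap resamples persist; "
                               "control cohort too small or constant")
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        s2, i2, v2 = _pair_fits_from_samples(data[idx_new])
        slopes[bad], intercepts[bad], var[bad] = s2, i2, v2
        bad = np.any(var == 0, axis=1)

    agg = np.mean if consensus == "mean" else np.median
    pairs = tuple(zip(*np.triu_indices(V, k=1)))
    return PairFitEnsemble(
        vois=tuple(vois),
        pairs=tuple((int(i), int(j)) for i, j in pairs),
        slopes=slopes, intercepts=intercepts,
        consensus_slope=agg(slopes, axis=0),
        consensus_intercept=agg(intercepts, axis=0),
        n_control=n, B=B, seed=int(seed), consensus=consensus,
        control_subjects=tuple(sorted(wide.index)),
    )
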