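"""The microglia desynchronization index (DI / connectivity deviation score).

A subject's regional uptake pattern is scored against the *control cohort's*
pairwise structure: for every VOI pair (i, j) the subject's point
(SUVR_i, SUVR_j) has a perpendicular (orthogonal) distance to the control
cohort's consensus regression line for that pair, and the DI of VOI *i* is
the sum of those distances over all pairs containing *i*.  A perfectly
"synchronized" subject — one lying on every control line — scores 0
everywhere; regional decoupling inflates the score.

Composite regions (whole cortex, the entorhinal–hippocampus–amygdala block)
are summarized by the first principal component of the constituent VOIs' DI
values across the cohort (standardized per VOI), with the sign oriented so
that higher scores mean more desynchronization.

The module exposes both the low-level operations and a statsmodels-style
pair: :class:`DesynchronizationModel` (data + control definition) whose
``fit`` returns a :class:`DesyncResults` carrying per-subject DI values,
composite PC1 scores, the control connectivity matrix, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .atlas import VOIAtlas
from .connectivity import (ConnectivityMatrix, PairFitEnsemble,
                           bootstrap_pair_fits, compute_icc_matrix)
from .tables import to_wide

__all__ = [
    "perpendicular_distance",
    "compute_di",
    "composite_pc1",
    "DesynchronizationModel",
    "DesyncResults",
]


def perpendicular_distance(point, line) -> float:
    """Orthogonal distance from ``point=(x0, y0)`` to ``y = b*x + a``.

    distance = |b*x0 - y0 + a| / sqrt(b^2 + 1); zero iff the point lies on
    the line.  ``line`` is (slope, intercept).
    """
    x0, y0 = point
    b, a = line
    vals = np.asarray([x0, y0, b, a], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite input: point={point}, line={line}")
    return float(abs(b * x0 - y0 + a) / np.hypot(b, 1.0))


def _pair_distances(profiles: np.ndarray, fits: PairFitEnsemble,
                    per_replicate: bool) -> np.ndarray:
    """Distances of shape (n_subjects, n_pairs).

    ``profiles``: (n, V) subject SUVR matrix in ensemble VOI order.  With
    ``per_replicate`` the distance of a pair is the mean over the B replicate
    lines instead of the distance to the consensus line.
    """
    iu = np.array([i for i, _ in fits.pairs])
    ju = np.array([j for _, j in fits.pairs])
    x = profiles[:, iu]                      # (n, P)
    y = profiles[:, ju]
    if per_replicate:
        b = fits.slopes[None, :, :]          # (1, B, P)
        a = fits.intercepts[None, :, :]
        d = np.abs(b * x[:, None, :] - y[:, None, :] + a) / np.hypot(b, 1.0)
        return d.mean(axis=1)
    b = fits.consensus_slope[None, :]
    a = fits.consensus_intercept[None, :]
    return np.abs(b * x - y + a) / np.hypot(b, 1.0)


def compute_di(profiles: pd.DataFrame, fits: PairFitEnsemble,
               per_replicate: bool = False) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject, per-VOI desynchronization index.

    ``profiles`` is a subject x VOI SUVR matrix (e.g. from
    :func:`petdesync.tables.to_wide`); its columns must cover the ensemble's
    VOIs.  Subjects with any missing VOI are skipped and reported in the
    second return value.  DI_i = sum over the V-1 pairs containing i of the
    perpendicular distance to that pair's control fit.
    """
    vois = list(fits.vois)
    missing_cols = [v for v in vois if v not in profiles.columns]
    if missing_cols:
        raise ValueError(f"profiles lack ensemble VOIs: {missing_cols}")
    sub = profiles.loc[:, vois]
    ok = sub.notna().all(axis=1)
    skipped = [{"subject_id": s,
                "missing_vois": sub.columns[sub.loc[s].isna()].tolist()}
               for s in sub.index[~ok]]
    sub = sub.loc[ok]
    d = _pair_distances(sub.to_numpy(dtype=float), fits, per_replicate)
    V = len(vois)
    di = np.zeros((len(sub), V))
    for p, (i, j) in enumerate(fits.pairs):
        di[:, i] += d[:, p]
        di[:, j] += d[:, p]
    out = pd.DataFrame(di, index=sub.index, columns=vois)
    out.index.name = "subject_id"
    return out, skipped


def composite_pc1(di: pd.DataFrame, constituents,
                  standardize: bool = True) -> tuple[pd.Series, float]:
    """First-principal-component composite of constituent-VOI DI values.

    Computed across the cohort on the subject x constituent matrix,
    standardized per VOI by default (DI scales differ across regions).  The
    score sign is oriented to correlate positively with the mean constituent
    DI, so the raw eigenvector's sign ambiguity never surfaces.  Returns
    (scores, explained variance fraction of PC1).

    A single constituent degenerates to its (standardized) DI with explained
    variance 1.
    """
    constituents = list(constituents)
    if not constituents:
        raise ValueError("composite needs >=1 constituent VOI")
    missing = [v for v in constituents if v not in di.columns]
    if missing:
        raise ValueError(f"constituent VOIs absent from DI table: {missing}")
    x = di.loc[:, constituents].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need >=3 subjects for a composite score")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = [v for v, s in zip(constituents, sd) if s == 0]
        raise ValueError(f"zero-variance constituents: {dead}")
    if standardize:
        x = (x - x.mean(axis=0)) / sd
    if x.shape[1] == 1:
        scores = x[:, 0]
        ev = 1.0
    else:
        pca = PCA(n_components=1, svd_solver="full")
        scores = pca.fit_transform(x)[:, 0]
        ev = float(pca.explained_variance_ratio_[0])
    mean_di = di.loc[:, constituents].mean(axis=1).to_numpy()
    c = np.corrcoef(scores, mean_di)[0, 1] if np.std(scores) > 0 else 0.0
    if c < 0:
        scores = -scores
    return pd.Series(scores, index=di.index, name="pc1"), ev


@dataclass
class DesyncResults:
    """Fitted desynchronization scores for a cohort.

    Attributes
    ----------
    di : per-subject, per-VOI raw distance sums.
    di_normalized : DI / (V-1), comparable across atlases.
    composites : per-subject PC1 scores, one column per composite.
    explained_variance : PC1 variance fraction per composite.
    connectivity : control-cohort interregional correlation matrix.
    fits : the bootstrap pair-fit ensemble the scores were measured against.
    """

    di: pd.DataFrame
    di_normalized: pd.DataFrame
    composites: pd.DataFrame
    explained_variance: dict[str, float]
    connectivity: ConnectivityMatrix
    fits: PairFitEnsemble
    skipped_subjects: list[dict] = field(default_factory=list)
    per_replicate: bool = False

    def summary(self) -> str:
        f = self.fits
        lines = [
            "Desynchronization index (connectivity deviation score)",
            f"  control cohort : n={f.n_control} subjects",
            f"  bootstrap      : B={f.B}, seed={f.seed}, consensus={f.consensus}",
            f"  distances      : {'per-replicate mean' if self.per_replicate else 'consensus fit'}",
            f"  VOIs / pairs   : {len(f.vois)} / {f.n_pairs}",
            f"  subjects scored: {len(self.di)}"
            + (f" ({len(self.skipped_subjects)} skipped, incomplete)" if self.skipped_subjects else ""),
            "",
            "  mean DI by VOI (top 5):",
        ]
        top = self.di.mean(axis=0).sort_values(ascending=False).head(5)
        lines += [f"    {v:24s} {m:8.4f}" for v, m in top.items()]
        for name in self.composites.columns:
            lines.append(
                f"  composite {name!r}: PC1 explained variance "
                f"{self.explained_variance[name]:.3f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long output table: per-subject DI (raw + normalized) and composites."""
        out = self.di.stack().rename("di").reset_index()
        out.columns = ["subject_id", "voi", "di"]
        out["di_normalized"] = self.di_normalized.stack().to_numpy()
        comp = self.composites.reset_index().melt(
            id_vars="subject_id", var_name="voi", value_name="di")
        comp["voi"] = "PC1:" + comp["voi"]
        comp["di_normalized"] = np.nan
        return pd.concat([out, comp], ignore_index=True)


class DesynchronizationModel:
    """Scores a cohort's regional coherence against a control cohort.

    Parameters
    ----------
    table
        Long-format SUVR uptake table (see :mod:`petdesync.tables`).
    atlas
        VOI atlas; target VOIs define the pair set, composites define the
        PC1 summaries.
    control_subjects
        Subjects whose scans define "synchronized" structure.  Default: all
        WT subjects in the table (pooled WT arms).
    age_months
        Timepoint at which connectivity and DI are computed.  Default: the
        latest age present.
    tracer
        Which tracer's SUVR to score (default TSPO).
    exclude_vois
        Target VOIs to leave out of the pair set — e.g. the SUVR reference
        region, which is constant 1 after scaling.
    """

    def __init__(self, table: pd.DataFrame, atlas: VOIAtlas,
                 control_subjects=None, age_months: float | None = None,
                 tracer: str = "TSPO", exclude_vois=()):
        if not (table["unit"] == "SUVR").all():
            raise ValueError("DesynchronizationModel expects a SUVR table")
        self.table = table
        self.atlas = atlas
        self.tracer = tracer
        self.age_months = (float(table["age_months"].max())
                           if age_months is None else float(age_months))
        if control_subjects is None:
            control_subjects = sorted(
                table.loc[table["genotype"] == "WT", "subject_id"].unique())
        self.control_subjects = tuple(control_subjects)
        self.vois = tuple(v for v in atlas.target_vois
                          if v not in set(exclude_vois))
        if len(self.vois) < 2:
            raise ValueError("need >=2 target VOIs after exclusions")

    def fit(self, B: int = 1000, seed: int = 0, consensus: str = "mean",
            per_replicate: bool = False,
            standardize_pc1: bool = True) -> DesyncResults:
        """Bootstrap the control pair fits and score every subject.

        ``per_replicate`` averages distances over the B replicate lines
        instead of using the consensus line; ``standardize_pc1`` toggles
        correlation- vs covariance-style composite PCA.
        """
        conn = compute_icc_matrix(self.table, self.control_subjects, self.vois,
                                  tracer=self.tracer, age_months=self.age_months)
        fits = bootstrap_pair_fits(self.table, self.control_subjects, self.vois,
                                   B=B, seed=seed, tracer=self.tracer,
                                   age_months=self.age_months,
                                   consensus=consensus)
        profiles = to_wide(self.table, tracer=self.tracer,
                           age_months=self.age_months, vois=self.vois)
        di, skipped = compute_di(profiles, fits, per_replicate=per_replicate)
        di_norm = di / (len(self.vois) - 1)
        comp_scores, evs = {}, {}
        for name, members in self.atlas.composites.items():
            usable = [v for v in members if v in di.columns]
            if not usable:
                continue
            comp_scores[name], evs[name] = composite_pc1(
                di, usable, standardize=standardize_pc1)
        composites = pd.DataFrame(comp_scores, index=di.index)
        return DesyncResults(di=di, di_normalized=di_norm, composites=composites,
                             explained_variance=evs, connectivity=conn,
                             fits=fits, skipped_subjects=skipped,
                             per_replicate=per_replicate)
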