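"""Regional PET quantification: %ID, pseudo-reference selection, SUVR, z-scores.

The quantification chain converts raw regional activity into comparable
uptake measures:

* ``%ID/cc`` — percent of the injected dose per cubic centimeter, a
  normalization-free measure used for global genotype contrasts.
* ``SUVR`` — uptake scaled to a *pseudo-reference* region assumed unaffected
  by disease.  For the inflammation tracer the reference is not assumed but
  *screened*: the VOI with the smallest absolute genotype effect size
  (Cohen's d on %ID) across candidates is selected.
* ``z-score`` — SUVR referenced to a control cohort's per-VOI mean/SD, so
  regional profiles of different tracers live on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import VOIAtlas

__all__ = [
    "compute_percent_id",
    "cohen_d",
    "select_pseudo_reference",
    "EffectSizeReport",
    "compute_suvr",
    "SUVRResult",
    "compute_zscores",
    "extract_voi_means",
]


def compute_percent_id(regional_concentration, injected_dose: float):
    """%ID/cc = 100 * concentration / injected dose.

    Both inputs must be decay-corrected to a common time and share activity
    units (e.g. kBq/cc and kBq).  Accepts a scalar, array, or a table with a
    ``value`` column (returned re-labelled as unit ``PCT_ID``).
    """
    if injected_dose <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose}")
    if isinstance(regional_concentration, pd.DataFrame):
        df = regional_concentration.copy()
        if (pd.to_numeric(df["value"]) < 0).any():
            raise ValueError("negative regional concentration")
        df["value"] = 100.0 * df["value"] / injected_dose
        df["unit"] = "PCT_ID"
        return df
    conc = np.asarray(regional_concentration, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative regional concentration")
    return 100.0 * conc / injected_dose


def cohen_d(group_a, group_b) -> float:
    """Cohen's d with the pooled sample SD (n-1 divisors).

    d = (mean_a - mean_b) / s_p,
    s_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 <= 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


@dataclass
class EffectSizeReport:
    """Per-candidate genotype effect sizes and the selected pseudo-reference."""

    effects: pd.DataFrame  # columns: voi, d, n_wt, n_ki
    selected_reference: str
    pooled_timepoints: bool = True

    def __str__(self) -> str:  # compact log form
        lines = [f"pseudo-reference screen ({'pooled' if self.pooled_timepoints else 'single'} timepoints)"]
        for rec in self.effects.sort_values("d", key=np.abs).itertuples(index=False):
            mark = " <- selected" if rec.voi == self.selected_reference else ""
            lines.append(f"  {rec.voi:24s} d={rec.d:+.3f} (nWT={rec.n_wt}, nKI={rec.n_ki}){mark}")
        return "\n".join(lines)


def select_pseudo_reference(table: pd.DataFrame, atlas: VOIAtlas,
                            candidates: list[str] | None = None,
                            timepoint: float | None = None) -> EffectSizeReport:
    """Screen candidate VOIs for the smallest |genotype effect| on %ID.

    Cohen's d (WT minus KI) is computed per candidate between all pooled WT
    and all pooled KI measurements; the VOI with smallest ``|d|`` becomes the
    pseudo-reference, ties broken lexicographically by VOI name.

    By default every VOI in the atlas is a candidate (the screen compares
    "every volume of interest") and all timepoints are pooled; pass
    ``timepoint`` to restrict the screen to one age.
    """
    if candidates is None:
        candidates = list(atlas.all_vois)
    if not candidates:
        raise ValueError("empty candidate list")
    sel = table[table["unit"] == "PCT_ID"]
    if timepoint is not None:
        sel = sel[sel["age_months"] == timepoint]
    recs = []
    for voi in candidates:
        sub = sel[sel["voi"] == voi]
        if sub.empty:
            raise ValueError(f"candidate VOI {voi!r} absent from table")
        wt = sub.loc[sub["genotype"] == "WT", "value"].to_numpy()
        ki = sub.loc[sub["genotype"] == "KI", "value"].to_numpy()
        if wt.size < 2 or ki.size < 2:
            raise ValueError(
                f"both genotypes need >=2 measurements for VOI {voi!r} "
                f"(got WT={wt.size}, KI={ki.size})")
        recs.append({"voi": voi, "d": cohen_d(wt, ki),
                     "n_wt": int(wt.size), "n_ki": int(ki.size)})
    effects = pd.DataFrame(recs)
    order = effects.assign(absd=effects["d"].abs()).sort_values(
        ["absd", "voi"], kind="mergesort")
    return EffectSizeReport(effects=effects,
                            selected_reference=str(order.iloc[0]["voi"]),
                            pooled_timepoints=timepoint is None)


@dataclass
class SUVRResult:
    """SUVR table plus the scans excluded for an unusable reference value."""

    table: pd.DataFrame
    reference_voi: str
    excluded_scans: list[dict] = field(default_factory=list)


def compute_suvr(table: pd.DataFrame, reference_voi: str) -> SUVRResult:
    """Scale each scan's VOI values by its own reference-VOI value.

    A *scan* is one (subject, tracer, timepoint).  Scans whose reference
    value is missing or non-positive are excluded and itemized in the result
    — never silently dropped.  The reference VOI itself maps to exactly 1.
    """
    if not (table["unit"] == "PCT_ID").all():
        raise ValueError("SUVR scaling expects a PCT_ID table")
    df = table.copy()
    scan_key = ["subject_id", "tracer", "age_months"]
    ref = df[df["voi"] == reference_voi].set_index(scan_key)["value"]
    keys = pd.MultiIndex.from_frame(df[scan_key])
    ref_vals = ref.reindex(keys).to_numpy()

    excluded = []
    usable = np.isfinite(ref_vals) & (ref_vals > 0)
    bad_scans = df.loc[~usable, scan_key].drop_duplicates()
    for rec in bad_scans.itertuples(index=False):
        rv = ref.get(tuple(rec), np.nan)
        excluded.append({"subject_id": rec.subject_id, "tracer": rec.tracer,
                         "age_months": rec.age_months,
                         "reason": ("reference VOI missing" if not np.isfinite(rv)
                                    else f"non-positive reference value {rv}")})
    df = df.loc[usable].copy()
    df["value"] = df["value"].to_numpy() / ref_vals[usable]
    df.loc[df["voi"] == reference_voi, "value"] = 1.0
    df["unit"] = "SUVR"
    return SUVRResult(table=df.reset_index(drop=True), reference_voi=reference_voi,
                      excluded_scans=excluded)


def compute_zscores(table: pd.DataFrame, control_subjects,
                    reference_age: float | None = None) -> pd.DataFrame:
    """Control-referenced z-scores from a SUVR table.

    Per-VOI mean and SD (n-1 divisor) are estimated from the control
    subjects at ``reference_age`` (default: the latest timepoint present)
    and applied to *every* scan in the table, so earlier timepoints are
    z-scored against the same late-age control statistics.
    """
    if not (table["unit"] == "SUVR").all():
        raise ValueError("z-scoring expects a SUVR table")
    control_subjects = set(control_subjects)
    if reference_age is None:
        reference_age = float(table["age_months"].max())
    ctrl = table[(table["subject_id"].isin(control_subjects))
                 & (table["age_months"] == reference_age)]
    present = set(ctrl["subject_id"].unique())
    absent = control_subjects - present
    if absent:
        raise ValueError(
            f"control subjects absent at reference age {reference_age}: "
            f"{sorted(absent)}")
    if len(present) < 3:
        raise ValueError("need >=3 control subjects at the reference timepoint")
    stats = ctrl.groupby("voi")["value"].agg(["mean", "std"])  # std: ddof=1
    zero_sd = stats.index[(stats["std"] == 0) | stats["std"].isna()].tolist()
    if zero_sd:
        raise ValueError(f"zero control SD in VOIs: {zero_sd}")
    df = table.copy()
    mu = df["voi"].map(stats["mean"])
    sigma = df["voi"].map(stats["std"])
    if mu.isna().any():
        missing = sorted(df.loc[mu.isna(), "voi"].unique())
        raise ValueError(f"no control statistics for VOIs: {missing}")
    df["value"] = (df["value"] - mu) / sigma
    df["unit"] = "ZSCORE"
    return df


def extract_voi_means_nifti(image_path, labels_path,
                            atlas: VOIAtlas) -> dict[str, float]:
    """Regional means from a NIfTI image plus integer label volume on disk.

    Thin wrapper over :func:`extract_voi_means` using nibabel; label data
    are rounded to the nearest integer to tolerate float-typed label maps.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    lab = nib.load(str(labels_path))
    labels = np.rint(np.asarray(lab.dataobj)).astype(int)
    return extract_voi_means(np.asarray(img.dataobj, dtype=float), labels,
                             atlas)


def extract_voi_means(image: np.ndarray, labels: np.ndarray,
                      atlas: VOIAtlas) -> dict[str, float]:
    """Mean image value per atlas VOI from an integer parcellation volume.

    ``labels`` assigns each voxel an integer VOI id (0 = background) per
    ``atlas.labels``.  Shapes must match; every atlas VOI must own >=1 voxel.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"image shape {image.shape} != labels shape {labels.shape}")
    if not atlas.labels:
        raise ValueError("atlas has no voi->label mapping")
    out = {}
    for voi, lab in atlas.labels.items():
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"label {lab} for VOI {voi!r} absent from volume")
        out[voi] = float(image[mask].mean())
    return out
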