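"""Synthetic preclinical PET cohort generator.

Emulates the statistical structure of a longitudinal, multi-arm TSPO-PET /
amyloid-PET mouse study — two genotypes (WT and an amyloidosis knock-in,
"KI"), four treatment arms (placebo, anti-amyloid antibody, pioglitazone,
and their combination), scans at 5, 7.5 and 10 months — so that every
downstream stage (pseudo-reference screening, SUVR, connectivity, the
desynchronization index, group statistics) can be tested by parameter
recovery against known ground truth.

Generative model for the inflammation tracer (``TSPO``), per subject *s*,
VOI *v*, age *t* (in %ID units)::

    y[s,v,t] = base[v]
             + L[v] * ( sqrt(1-delta_s) * F[s,t] + sqrt(delta_s) * G[s,v,t] )
             + slope[v] * mult[arm_s] * (t - t0) * [s is KI]
             + eps[s,v,t]

where ``F`` is a shared per-subject activation factor (the source of
interregional correlation), ``G`` is independent per-VOI noise of matched
unit variance, and ``delta_s`` (the *desynchronization fraction*, per arm)
replaces the shared component by idiosyncratic noise while preserving the
marginal variance — so increasing delta destroys covariance, not scale.

The amyloid tracer (``ABETA``) is pure noise around its baseline in WT
(amyloid-negative) animals; in KI animals its regional deviation couples to
the subject's TSPO deviation with per-arm, per-timepoint strength ``kappa``
(on a correlation scale, so kappa approximates the pooled subject-by-region
correlation between the two tracers' z-profiles).

Behavior (water-maze target-quadrant time) is a genotype intercept plus
``behavior_beta[arm]`` (seconds per SD) times the subject's cortical
desynchronization proxy — the subject's *true* DI at the final timepoint,
scored against the analytic WT population regression lines and standardized
within arm — plus noise, floored at zero.  With noise SD sigma_b, the
population R² of the behavior link in an arm is beta² / (beta² + sigma_b²).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import CORTICAL_VOIS, default_atlas

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "apply_missingness",
]

GENOTYPES = ("WT", "KI")
TREATMENTS = ("PL/PL", "Ab/PL", "PL/Pio", "Ab/Pio")
#: Canonical arm labels: "<genotype> <treatment>".
ARMS = tuple(f"{g} {t}" for g in GENOTYPES for t in TREATMENTS)

_POSITIVITY_FLOOR = 0.01  # fraction of base_mean below which uptake is clipped


def _split_arm(arm: str) -> tuple[str, str]:
    try:
        genotype, treatment = arm.split(" ", 1)
    except ValueError:
        raise ValueError(f"unknown arm {arm!r}; expected '<genotype> <treatment>'")
    if genotype not in GENOTYPES or treatment not in TREATMENTS:
        raise ValueError(f"unknown arm {arm!r}")
    return genotype, treatment


@dataclass
class SyntheticConfig:
    """Full generative parameterization of a simulated cohort.

    All per-VOI mappings must cover every name in ``vois``; per-arm mappings
    must cover every arm in ``n_per_arm``.
    """

    n_per_arm: dict[str, int]
    vois: tuple[str, ...]
    timepoints: tuple[float, ...] = (5.0, 7.5, 10.0)
    t0: float = 5.0
    base_mean: dict[str, float] = field(default_factory=dict)
    latent_loadings: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    genotype_slope: dict[str, float] = field(default_factory=dict)
    treatment_multiplier: dict[str, float] = field(default_factory=dict)
    desync_delta: dict[str, float] = field(default_factory=dict)
    coupling_kappa: dict[str, dict[float, float]] = field(default_factory=dict)
    behavior_beta: dict[str, float] = field(default_factory=dict)
    behavior_intercept: dict[str, float] = field(
        default_factory=lambda: {"WT": 25.0, "KI": 18.0}
    )
    behavior_noise_sd: float = 5.0
    abeta_base_mean: dict[str, float] = field(default_factory=dict)
    abeta_noise_sd: dict[str, float] = field(default_factory=dict)
    missing_rate: dict[float, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.vois)) != len(self.vois):
            raise ValueError("duplicate VOI names")
        for arm in self.n_per_arm:
            _split_arm(arm)
        tps = tuple(float(t) for t in self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints = tps
        for v in self.vois:
            if self.base_mean.get(v, 1.0) <= 0:
                raise ValueError(f"non-positive base_mean for VOI {v!r}")
            if self.noise_sd.get(v, 0.0) < 0:
                raise ValueError(f"negative noise_sd for VOI {v!r}")
        for arm, d in self.desync_delta.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"desync_delta for {arm!r} must be in [0,1]")
        for t, r in self.missing_rate.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing_rate for timepoint {t} must be in [0,1)")

    # -- convenience accessors with validation -------------------------------
    def delta(self, arm: str) -> float:
        return float(self.desync_delta.get(arm, 0.0))

    def kappa(self, arm: str, t: float) -> float:
        _, treatment = _split_arm(arm)
        per_arm = self.coupling_kappa.get(arm, self.coupling_kappa.get(treatment, {}))
        return float(per_arm.get(t, 0.0))

    def total_sd(self, voi: str) -> float:
        return math.hypot(self.latent_loadings[voi], self.noise_sd[voi])

    def expected_mean(self, arm: str, voi: str, t: float) -> float:
        """Analytic mean TSPO %ID for (arm, VOI, timepoint)."""
        genotype, treatment = _split_arm(arm)
        mu = self.base_mean[voi]
        if genotype == "KI":
            mult = self.treatment_multiplier.get(treatment, 1.0)
            mu += self.genotype_slope.get(voi, 0.0) * mult * (t - self.t0)
        return mu

    def to_json(self) -> str:
        def _enc(obj):
            if isinstance(obj, tuple):
                return list(obj)
            raise TypeError(type(obj))
        d = {k: v for k, v in self.__dict__.items()}
        # JSON object keys must be strings; timepoint-keyed maps need encoding
        d["coupling_kappa"] = {
            a: {str(t): k for t, k in m.items()} for a, m in self.coupling_kappa.items()
        }
        d["missing_rate"] = {str(t): r for t, r in self.missing_rate.items()}
        return json.dumps(d, default=_enc, sort_keys=True)


def default_config(**overrides) -> SyntheticConfig:
    """The study-shaped default cohort.

    Cohort sizes follow the 10-month arms of the emulated study; target-VOI
    between-subject variability is 25% of the regional mean with 70% of that
    variance carried by the shared activation factor (control interregional
    r ~ 0.7); reference regions (brainstem, periaqueductal gray) are
    disease-spared: no genotype slope, tight noise, weak factor loading.
    Genotype effects reach +45%..+90% of baseline by 10 months across target
    VOIs; treatment multipliers scale them per arm; desynchronization,
    tracer coupling and the behavior link are arm-specific (see
    docs/methods.md for the rationale behind each value).
    """
    atlas = default_atlas()
    vois = atlas.all_vois
    targets = atlas.target_vois
    refs = atlas.reference_candidates

    base = {v: round(0.55 + 0.015 * i, 4) for i, v in enumerate(targets)}
    base.update({"brainstem": 0.70, "periaqueductal_gray": 0.60})

    loadings, noise = {}, {}
    for v in targets:
        cov = 0.25 * base[v]
        loadings[v] = cov * math.sqrt(0.7)
        noise[v] = cov * math.sqrt(0.3)
    # reference regions: disease-spared and low-variability (CoV 6%) — the
    # property that makes them usable for SUVR scaling at all
    for v in refs:
        cov = 0.06 * base[v]
        loadings[v] = cov * math.sqrt(0.25)
        noise[v] = cov * math.sqrt(0.75)

    # relative 10-month genotype effect spread across target VOIs (0.45..0.90)
    rel = np.linspace(0.45, 0.90, len(targets))
    slope = {v: float(r) * base[v] / 5.0 for v, r in zip(targets, rel)}
    slope.update({v: 0.0 for v in refs})

    cfg = SyntheticConfig(
        n_per_arm={
            "WT PL/PL": 8, "WT Ab/PL": 6,
            "KI PL/PL": 8, "KI Ab/PL": 12, "KI PL/Pio": 10, "KI Ab/Pio": 18,
        },
        vois=vois,
        base_mean=base,
        latent_loadings=loadings,
        noise_sd=noise,
        genotype_slope=slope,
        treatment_multiplier={"PL/PL": 1.0, "Ab/PL": 0.45, "PL/Pio": 0.70,
                              "Ab/Pio": 0.50},
        desync_delta={"WT PL/PL": 0.0, "WT Ab/PL": 0.0,
                      "KI PL/PL": 0.5, "KI Ab/PL": 0.6,
                      "KI PL/Pio": 0.35, "KI Ab/Pio": 0.35},
        coupling_kappa={
            "PL/PL": {5.0: 0.14, 7.5: 0.14, 10.0: 0.10},
            "Ab/PL": {5.0: 0.14, 7.5: 0.56, 10.0: 0.37},
            "PL/Pio": {5.0: 0.14, 7.5: 0.47, 10.0: 0.33},
            "Ab/Pio": {5.0: 0.14, 7.5: 0.39, 10.0: 0.50},
        },
        behavior_beta={"KI Ab/PL": -6.0},
        abeta_base_mean={v: round(0.6 * base[v], 4) for v in vois},
        # amyloid reference regions are disease-spared and low-noise (CoV 5%)
        # so reference scaling does not drown the regional coupling signal
        abeta_noise_sd={v: round((0.03 if v in refs else 0.09) * base[v], 4)
                        for v in vois},
        missing_rate={5.0: 0.0, 7.5: 0.3, 10.0: 0.1},
        seed=0,
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg


@dataclass
class SyntheticCohort:
    """Generated cohort: uptake + behavior tables and the generative truth.

    ``truth`` carries the per-subject latent state (desync fraction, cortical
    desynchronization proxy) and the config, sufficient to recompute expected
    group means analytically via ``config.expected_mean``.
    """

    uptake: pd.DataFrame
    behavior: pd.DataFrame
    truth: dict
    config: SyntheticConfig

    def truth_json(self) -> str:
        t = dict(self.truth)
        t["subjects"] = self.truth["subjects"].to_dict(orient="records")
        t["config"] = json.loads(self.config.to_json())
        return json.dumps(t, sort_keys=True)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (both tracers, all timepoints, behavior).

    Identical ``config`` (including ``seed``) yields bit-identical tables.
    Missingness is NOT applied here; see :func:`apply_missingness`.
    """
    vois = list(config.vois)
    V = len(vois)
    base = np.array([config.base_mean[v] for v in vois])
    L = np.array([config.latent_loadings[v] for v in vois])
    sd = np.array([config.noise_sd[v] for v in vois])
    slope = np.array([config.genotype_slope.get(v, 0.0) for v in vois])
    tot_sd = np.sqrt(L**2 + sd**2)
    ab_base = np.array([config.abeta_base_mean.get(v, 0.6 * config.base_mean[v])
                        for v in vois])
    ab_sd = np.array([config.abeta_noise_sd.get(v, 0.15 * abm)
                      for v, abm in zip(vois, ab_base)])
    cortical_idx = [i for i, v in enumerate(vois) if v in CORTICAL_VOIS]

    arms = sorted(config.n_per_arm)  # deterministic subject order
    root = np.random.SeedSequence(config.seed)
    n_subjects = sum(config.n_per_arm.values())
    children = root.spawn(n_subjects)

    # Analytic WT population regression lines (delta=0 control structure) for
    # the behavior proxy: line of VOI j on cortical VOI i has slope
    # cov/var = L_i L_j / (L_i^2 + sd_i^2) and passes through the base means.
    if cortical_idx:
        ci = np.array(cortical_idx)
        line_b = (L[ci, None] * L[None, :]) / (L[ci] ** 2 + sd[ci] ** 2)[:, None]
        line_a = base[None, :] - line_b * base[ci, None]
        line_norm = np.hypot(line_b, 1.0)

    def _true_cortical_di(y: np.ndarray) -> float:
        """Mean over cortical VOIs of the summed perpendicular distances of
        the subject's %ID pair points to the population control lines."""
        if not cortical_idx:
            return 0.0
        d = np.abs(line_b * y[ci, None] - y[None, :] + line_a) / line_norm
        d[np.arange(len(ci)), ci] = 0.0
        return float(d.sum(axis=1).mean())

    rows: list[tuple] = []
    subj_records: list[dict] = []
    behav_rows: list[tuple] = []
    clipped = 0
    si = 0
    for arm in arms:
        genotype, treatment = _split_arm(arm)
        mult = config.treatment_multiplier.get(treatment, 1.0)
        delta = config.delta(arm)
        slug = arm.replace(" ", "-").replace("/", "")
        arm_entries: list[dict] = []
        for i in range(config.n_per_arm[arm]):
            sid = f"{slug}_{i:02d}"
            rng = np.random.default_rng(children[si])
            si += 1
            proxy = 0.0
            for t in config.timepoints:
                F = rng.standard_normal()
                G = rng.standard_normal(V)
                eps = rng.standard_normal(V) * sd
                ab_eps = rng.standard_normal(V)
                latent = L * (math.sqrt(1.0 - delta) * F + math.sqrt(delta) * G)
                eff = slope * mult * (t - config.t0) if genotype == "KI" else 0.0
                y = base + latent + eff + eps
                lo = _POSITIVITY_FLOOR * base
                clipped += int(np.sum(y < lo))
                y = np.maximum(y, lo)

                kappa = config.kappa(arm, t)
                if genotype == "KI" and kappa != 0.0:
                    dev_z = (y - base) / tot_sd
                    ab_dev = kappa * dev_z + math.sqrt(1.0 - kappa**2) * ab_eps
                else:
                    ab_dev = ab_eps
                ya = np.maximum(ab_base + ab_sd * ab_dev, _POSITIVITY_FLOOR * ab_base)

                for j, v in enumerate(vois):
                    rows.append((sid, genotype, treatment, t, "TSPO", v, y[j]))
                    rows.append((sid, genotype, treatment, t, "ABETA", v, ya[j]))
                if t == config.timepoints[-1]:
                    proxy = _true_cortical_di(y)
            arm_entries.append({"sid": sid, "proxy": proxy,
                                "noise": rng.standard_normal()})

        # behavior links to the within-arm standardized proxy so behavior_beta
        # is in seconds per SD of true desynchronization severity
        proxies = np.array([e["proxy"] for e in arm_entries])
        psd = proxies.std(ddof=1) if len(proxies) >= 2 else 0.0
        zproxy = (proxies - proxies.mean()) / psd if psd > 0 else np.zeros_like(proxies)
        beta = config.behavior_beta.get(arm, 0.0)
        for e, zp in zip(arm_entries, zproxy):
            q = (config.behavior_intercept[genotype]
                 + beta * zp
                 + e["noise"] * config.behavior_noise_sd)
            q = max(q, 0.0)
            behav_rows.append((e["sid"], q, treatment, genotype))
            subj_records.append({"subject_id": e["sid"], "genotype": genotype,
                                 "arm": treatment, "delta": delta,
                                 "behavior_proxy": e["proxy"],
                                 "quadrant_time": q})

    uptake = pd.DataFrame(rows, columns=["subject_id", "genotype", "arm",
                                         "age_months", "tracer", "voi", "value"])
    uptake["unit"] = "PCT_ID"
    behavior = pd.DataFrame(behav_rows,
                            columns=["subject_id", "quadrant_time", "arm", "genotype"])
    truth = {
        "subjects": pd.DataFrame(subj_records),
        "n_clipped_values": clipped,
        "seed": config.seed,
    }
    return SyntheticCohort(uptake=uptake, behavior=behavior, truth=truth,
                           config=config)


def apply_missingness(cohort: SyntheticCohort,
                      config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Remove whole scans (subject, tracer, timepoint) completely at random.

    Each non-baseline scan is dropped independently with the per-timepoint
    ``missing_rate``; first-timepoint scans are never dropped, so every
    subject retains baseline coverage.  Rates >= 0.9 are rejected: the
    coverage guarantee would be meaningless at near-total missingness.
    Reproducible: the removal mask derives from ``config.seed`` only.
    """
    config = config or cohort.config
    if not config.missing_rate:
        return cohort
    for t, r in config.missing_rate.items():
        if r >= 0.9:
            raise ValueError(
                f"missing_rate {r} at timepoint {t}: baseline/coverage "
                "protection unsatisfiable at near-total missingness")
    baseline = config.timepoints[0]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 710_113]))
    up = cohort.uptake
    scans = up[["subject_id", "tracer", "age_months"]].drop_duplicates()
    scans = scans.sort_values(["subject_id", "tracer", "age_months"],
                              kind="mergesort").reset_index(drop=True)
    rates = scans["age_months"].map(lambda t: config.missing_rate.get(t, 0.0)).to_numpy()
    drop = rng.random(len(scans)) < rates
    drop &= (scans["age_months"] != baseline).to_numpy()
    dropped = scans[drop]
    key = pd.MultiIndex.from_frame(up[["subject_id", "tracer", "age_months"]])
    bad = key.isin(pd.MultiIndex.from_frame(dropped))
    pruned = up[~bad].reset_index(drop=True)
    truth = dict(cohort.truth)
    truth["n_scans_dropped"] = int(drop.sum())
    return SyntheticCohort(uptake=pruned, behavior=cohort.behavior, truth=truth,
                           config=config)
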