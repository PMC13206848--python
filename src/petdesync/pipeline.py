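"""End-to-end pipeline: simulate -> quantify -> connect -> desync -> stats.

Each stage reads/writes the shared long-format CSV tables and a JSON
manifest records every input, output, seed and content digest, so a re-run
with an identical configuration reproduces identical digests (the
determinism contract of the whole artifact: all randomness flows from the
single configured seed, never from global RNG state).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import VOIAtlas, default_atlas
from .desync import DesynchronizationModel
from .group_stats import (behavior_correlation, fdr_adjust, kruskal_wallis,
                          mwu_test, regional_coupling)
from .quantification import compute_suvr, compute_zscores, select_pseudo_reference
from .synthetic import SyntheticConfig, apply_missingness, default_config, generate_cohort
from .tables import validate_table, write_table

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "quantify", "connect", "desync", "stats")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    B: int = 1000
    tspo_reference: str = "auto"       # VOI name, or "auto" for the d-screen
    abeta_reference: str = "periaqueductal_gray"
    consensus: str = "mean"
    per_replicate: bool = False
    standardize_pc1: bool = True
    with_missingness: bool = False
    uptake_path: str | None = None     # required when 'simulate' not requested
    behavior_path: str | None = None
    synthetic_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig, atlas: VOIAtlas | None = None,
                 synthetic_config: SyntheticConfig | None = None) -> dict:
    """Execute the requested stages and return the manifest.

    Outputs land in ``config.out_dir``; the manifest (also written there as
    ``manifest.json``) lists the stages run, all output files with SHA-256
    digests, and the seeds/flags that produced them.
    """
    atlas = atlas or default_atlas()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": list(config.stages),
                      "seed": config.seed, "B": config.B,
                      "flags": {"consensus": config.consensus,
                                "per_replicate": config.per_replicate,
                                "standardize_pc1": config.standardize_pc1,
                                "tspo_reference": config.tspo_reference,
                                "abeta_reference": config.abeta_reference},
                      "inputs": {}, "outputs": {}}

    def _emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = _sha256(path)

    # ---- simulate ----------------------------------------------------------
    behavior = None
    if "simulate" in config.stages:
        scfg = synthetic_config or default_config(
            seed=config.seed, **config.synthetic_overrides)
        cohort = generate_cohort(scfg)
        if config.with_missingness:
            cohort = apply_missingness(cohort)
        uptake = cohort.uptake
        behavior = cohort.behavior
        write_table(uptake, out / "uptake.csv")
        behavior.sort_values("subject_id", kind="mergesort").to_csv(
            out / "behavior.csv", index=False, float_format="%.10g")
        (out / "truth.json").write_text(cohort.truth_json() + "\n")
        for f in ("uptake.csv", "behavior.csv", "truth.json"):
            _emit(f, out / f)
    else:
        if not config.uptake_path:
            raise PipelineError("simulate", "no uptake_path and simulate not requested")
        uptake = validate_table(config.uptake_path)
        manifest["inputs"]["uptake"] = _sha256(Path(config.uptake_path))
        if config.behavior_path:
            behavior = pd.read_csv(config.behavior_path)
            manifest["inputs"]["behavior"] = _sha256(Path(config.behavior_path))

    # ---- quantify ----------------------------------------------------------
    suvr_tspo = suvr_abeta = z_tspo = z_abeta = None
    if "quantify" in config.stages:
        tspo = uptake[uptake["tracer"] == "TSPO"]
        if config.tspo_reference == "auto":
            try:
                report = select_pseudo_reference(tspo, atlas)
            except ValueError as e:
                raise PipelineError("quantify", str(e)) from e
            ref = report.selected_reference
            _json_dump({"selected_reference": ref,
                        "effects": report.effects.to_dict(orient="records")},
                       out / "reference_screen.json")
            _emit("reference_screen.json", out / "reference_screen.json")
        else:
            ref = config.tspo_reference
        if ref not in set(tspo["voi"]):
            raise PipelineError("quantify", f"reference VOI {ref!r} absent from table")
        res_t = compute_suvr(tspo, ref)
        suvr_tspo = res_t.table
        abeta = uptake[uptake["tracer"] == "ABETA"]
        exclusions = list(res_t.excluded_scans)
        if not abeta.empty:
            res_a = compute_suvr(abeta, config.abeta_reference)
            suvr_abeta = res_a.table
            exclusions += res_a.excluded_scans
        suvr_all = pd.concat([t for t in (suvr_tspo, suvr_abeta) if t is not None],
                             ignore_index=True)
        write_table(suvr_all, out / "suvr.csv")
        _emit("suvr.csv", out / "suvr.csv")
        if exclusions:
            _json_dump(exclusions, out / "suvr_exclusions.json")
            _emit("suvr_exclusions.json", out / "suvr_exclusions.json")

        controls = sorted(suvr_tspo.loc[suvr_tspo["genotype"] == "WT",
                                        "subject_id"].unique())
        z_frames = []
        try:
            # reference VOIs are identically 1 after scaling; z-score the rest
            z_tspo = compute_zscores(suvr_tspo[suvr_tspo["voi"] != ref], controls)
            z_frames.append(z_tspo)
            if suvr_abeta is not None:
                ctrl_a = sorted(suvr_abeta.loc[suvr_abeta["genotype"] == "WT",
                                               "subject_id"].unique())
                z_abeta = compute_zscores(
                    suvr_abeta[suvr_abeta["voi"] != config.abeta_reference],
                    ctrl_a)
                z_frames.append(z_abeta)
        except ValueError as e:
            raise PipelineError("quantify", f"z-scoring: {e}") from e
        write_table(pd.concat(z_frames, ignore_index=True), out / "zscores.csv")
        _emit("zscores.csv", out / "zscores.csv")

    # ---- connect + desync (DesynchronizationModel does both) ---------------
    results = None
    if "desync" in config.stages or "connect" in config.stages:
        if suvr_tspo is None:
            raise PipelineError("connect", "quantify stage must run first "
                                "(no SUVR table available)")
        try:
            # `ref` (the TSPO SUVR reference) is constant 1 after scaling and
            # must not enter the pair set when the screen picked a target VOI
            model = DesynchronizationModel(suvr_tspo, atlas,
                                           exclude_vois=(ref,))
            results = model.fit(B=config.B, seed=config.seed,
                                consensus=config.consensus,
                                per_replicate=config.per_replicate,
                                standardize_pc1=config.standardize_pc1)
        except ValueError as e:
            raise PipelineError("desync", str(e)) from e
        conn = results.connectivity
        conn.to_frame("r").to_csv(out / "connectivity_r.csv", float_format="%.10g")
        conn.to_frame("z").to_csv(out / "connectivity_z.csv", float_format="%.10g")
        _json_dump({"n_subjects": conn.n_subjects, **results.fits.metadata()},
                   out / "connectivity_meta.json")
        for f in ("connectivity_r.csv", "connectivity_z.csv",
                  "connectivity_meta.json"):
            _emit(f, out / f)
        if "desync" in config.stages:
            results.to_frame().to_csv(out / "desync.csv", index=False,
                                      float_format="%.10g")
            _json_dump({"explained_variance": results.explained_variance,
                        "skipped": results.skipped_subjects,
                        **results.fits.metadata()}, out / "desync_meta.json")
            _emit("desync.csv", out / "desync.csv")
            _emit("desync_meta.json", out / "desync_meta.json")

    # ---- stats -------------------------------------------------------------
    if "stats" in config.stages:
        stats_out = _stats_stage(uptake, suvr_tspo, z_tspo, z_abeta, results,
                                 behavior, atlas)
        _json_dump(stats_out, out / "stats.json")
        _emit("stats.json", out / "stats.json")

    _json_dump(manifest, out / "manifest.json")
    return manifest


def _stats_stage(uptake, suvr_tspo, z_tspo, z_abeta, desync_results,
                 behavior, atlas) -> dict:
    """The descriptive/inferential battery on whatever inputs are available.

    Families (one FDR adjustment each, mirroring per-panel correction):
    per-VOI genotype MWU contrasts on %ID at the final age; per-VOI
    Kruskal-Wallis across arms; regional tracer coupling per arm/timepoint;
    behavior correlations per arm against the cortical DI composite.
    """
    final_age = float(uptake["age_months"].max())
    pid = uptake[(uptake["unit"] == "PCT_ID") & (uptake["tracer"] == "TSPO")
                 & (uptake["age_months"] == final_age)]
    out: dict = {"final_age_months": final_age, "families": {}}

    contrasts = []
    for voi in atlas.target_vois:
        sub = pid[pid["voi"] == voi]
        wt = sub.loc[sub["genotype"] == "WT", "value"].to_numpy()
        ki = sub.loc[sub["genotype"] == "KI", "value"].to_numpy()
        if wt.size and ki.size:
            contrasts.append(mwu_test(wt, ki, comparison=f"{voi}: WT vs KI"))
    if contrasts:
        adj = fdr_adjust([c.p for c in contrasts])
        for c, pa in zip(contrasts, adj):
            c.p_adjusted = float(pa)
        out["families"]["genotype_mwu_pct_id"] = [c.as_dict() for c in contrasts]

    kw = []
    for voi in atlas.target_vois:
        sub = pid[pid["voi"] == voi]
        groups = [g["value"].to_numpy()
                  for _, g in sub.groupby(["genotype", "arm"]) if len(g)]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 5:
            try:
                kw.append(kruskal_wallis(groups, comparison=f"{voi}: all arms"))
            except ValueError:
                continue
    if kw:
        adj = fdr_adjust([c.p for c in kw])
        for c, pa in zip(kw, adj):
            c.p_adjusted = float(pa)
        out["families"]["arm_kruskal_pct_id"] = [c.as_dict() for c in kw]

    if suvr_tspo is not None and suvr_tspo["age_months"].nunique() >= 2:
        from .atlas import CORTICAL_VOIS
        from .group_stats import baseline_change_regression
        ages = sorted(suvr_tspo["age_months"].unique())
        cort = suvr_tspo[suvr_tspo["voi"].isin(CORTICAL_VOIS)]
        per_scan = cort.groupby(["genotype", "arm", "subject_id",
                                 "age_months"])["value"].mean()
        fits = []
        for (g, arm), sub in per_scan.groupby(level=["genotype", "arm"]):
            sub = sub.droplevel(["genotype", "arm"]).unstack("age_months")
            if ages[0] not in sub.columns or ages[-1] not in sub.columns:
                continue
            paired = sub[[ages[0], ages[-1]]].dropna()
            if len(paired) < 3:
                continue
            fits.append(baseline_change_regression(
                paired[ages[0]], paired[ages[-1]],
                label=f"{g} {arm}: cortex {ages[0]}->{ages[-1]} M").as_dict())
        if fits:
            out["families"]["baseline_change_cortex_suvr"] = fits

    if z_tspo is not None and z_abeta is not None:
        fits = []
        kis_t = z_tspo[(z_tspo["genotype"] == "KI")
                       & (z_tspo["voi"].isin(atlas.target_vois))]
        kis_a = z_abeta[(z_abeta["genotype"] == "KI")
                        & (z_abeta["voi"].isin(atlas.target_vois))]
        for (arm, age), sub_t in kis_t.groupby(["arm", "age_months"]):
            sub_a = kis_a[(kis_a["arm"] == arm) & (kis_a["age_months"] == age)]
            if len(sub_a) >= 3 and len(sub_t) >= 3:
                try:
                    fits.append(regional_coupling(
                        sub_t, sub_a, label=f"{arm} @ {age} M").as_dict())
                except ValueError:
                    continue
        out["families"]["regional_coupling"] = fits

    if desync_results is not None and behavior is not None \
            and "cortex" in desync_results.composites.columns:
        ki_behavior = behavior[behavior["genotype"] == "KI"]
        res = behavior_correlation(desync_results.composites["cortex"],
                                   ki_behavior)
        out["families"]["behavior_vs_cortical_di"] = {
            k: v.as_dict() for k, v in res.items()}
    return out
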