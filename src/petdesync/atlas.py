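"""Volume-of-interest (VOI) atlas definitions.

The analysis operates on regional uptake means over an atlas parcellation of
the mouse brain (Ma–Benveniste–Mirrione-style), with the neocortical target
region subdivided into bilateral functional areas.  An atlas here is just the
bookkeeping the pipeline needs: which VOIs are disease targets, which are
candidate pseudo-reference regions, how composite regions (whole cortex, the
entorhinal–hippocampus–amygdala "EHA" block) are assembled, and — for the
optional imaging path — which integer label in a parcellation volume each VOI
corresponds to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["VOIAtlas", "default_atlas", "CORTICAL_VOIS", "EHA_VOIS"]

#: Bilateral neocortical subdivisions (10 VOIs) forming the "cortex" composite.
CORTICAL_VOIS: tuple[str, ...] = tuple(
    f"{area}_{side}"
    for area in (
        "visual_ctx",
        "auditory_ctx",
        "entorhinal_ctx",
        "sensorimotor_ctx",
        "somatosensory_ctx",
    )
    for side in ("l", "r")
)

#: Constituents of the entorhinal–hippocampus–amygdala composite.
EHA_VOIS: tuple[str, ...] = (
    "entorhinal_ctx_l",
    "entorhinal_ctx_r",
    "hippocampus_l",
    "hippocampus_r",
    "amygdala_l",
    "amygdala_r",
)

_SUBCORTICAL: tuple[str, ...] = (
    "hippocampus_l",
    "hippocampus_r",
    "amygdala_l",
    "amygdala_r",
    "thalamus_l",
    "thalamus_r",
    "striatum_l",
    "striatum_r",
    "hypothalamus_l",
    "hypothalamus_r",
)


@dataclass(frozen=True)
class VOIAtlas:
    """A named parcellation: target VOIs, reference candidates, composites.

    Parameters
    ----------
    target_vois
        Regions analysed for disease signal.
    reference_candidates
        Regions eligible as a pseudo-reference for SUVR scaling.  Disjoint
        from ``target_vois``.
    composites
        Mapping composite-name -> constituent VOI names.  Constituents must
        be defined VOIs.
    labels
        Optional mapping VOI -> integer label in a parcellation volume
        (for the NIfTI extraction path).  Label 0 is background.
    """

    target_vois: tuple[str, ...]
    reference_candidates: tuple[str, ...]
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.target_vois)) != len(self.target_vois):
            raise ValueError("duplicate target VOI names")
        overlap = set(self.target_vois) & set(self.reference_candidates)
        if overlap:
            raise ValueError(f"target and reference sets overlap: {sorted(overlap)}")
        known = set(self.all_vois)
        for name, members in self.composites.items():
            missing = set(members) - known
            if missing:
                raise ValueError(
                    f"composite {name!r} references undefined VOIs: {sorted(missing)}"
                )
        if self.labels:
            vals = list(self.labels.values())
            if 0 in vals:
                raise ValueError("label 0 is reserved for background")
            if len(set(vals)) != len(vals):
                raise ValueError("duplicate integer labels in atlas")

    @property
    def all_vois(self) -> tuple[str, ...]:
        return tuple(self.target_vois) + tuple(self.reference_candidates)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_vois": list(self.target_vois),
            "reference_candidates": list(self.reference_candidates),
            "composites": {k: list(v) for k, v in self.composites.items()},
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "VOIAtlas":
        payload = json.loads(Path(path).read_text())
        return cls(
            target_vois=tuple(payload["target_vois"]),
            reference_candidates=tuple(payload["reference_candidates"]),
            composites={k: tuple(v) for k, v in payload.get("composites", {}).items()},
            labels={k: int(v) for k, v in payload.get("labels", {}).items()},
        )


def default_atlas() -> VOIAtlas:
    """The 20-target mouse atlas used throughout: 10 bilateral neocortical
    subdivisions plus 10 bilateral subcortical regions, with brainstem and
    periaqueductal gray as pseudo-reference candidates and the cortex / EHA
    composites predefined."""
    targets = CORTICAL_VOIS + _SUBCORTICAL
    refs = ("brainstem", "periaqueductal_gray")
    labels = {v: i + 1 for i, v in enumerate(targets + refs)}
    return VOIAtlas(
        target_vois=targets,
        reference_candidates=refs,
        composites={"cortex": CORTICAL_VOIS, "EHA": EHA_VOIS},
        labels=labels,
    )
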