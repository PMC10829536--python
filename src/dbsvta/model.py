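"""Tissue label conventions and the volume-conductor model type."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "TissueModel",
    "EXTERIOR",
    "AVERAGE_BODY",
    "SKULL",
    "GRAY_MATTER",
    "WHITE_MATTER",
    "CSF",
    "VENTRICLE",
    "LEAD_SHAFT",
    "LEAD_CONTACT",
    "LEAD_ACTIVE",
    "TISSUE_LABELS",
    "CONDUCTOR_SIGMA",
]

# anatomical labels
EXTERIOR = 0  # air / outside the body, sigma = 0
AVERAGE_BODY = 1
SKULL = 2
GRAY_MATTER = 3
WHITE_MATTER = 4
CSF = 5
VENTRICLE = 6

# lead labels written by rasterization
LEAD_SHAFT = 90  # insulator, sigma = 0
LEAD_CONTACT = 91  # non-active metal contact
LEAD_ACTIVE = 92  # active (source) contact

#: canonical tissue-name -> label mapping used by phantom specs / configs
TISSUE_LABELS: dict[str, int] = {
    "Exterior": EXTERIOR,
    "AverageBody": AVERAGE_BODY,
    "Skull": SKULL,
    "BrainGreyMatter": GRAY_MATTER,
    "BrainWhiteMatter": WHITE_MATTER,
    "CerebroSpinalFluid": CSF,
    "Ventricle": VENTRICLE,
    "LeadShaft": LEAD_SHAFT,
    "LeadContact": LEAD_CONTACT,
    "LeadActive": LEAD_ACTIVE,
}

#: conductivity of metal contacts, S/m
CONDUCTOR_SIGMA = 4.0e6

_INSULATOR_LABELS = frozenset({EXTERIOR, LEAD_SHAFT})


@dataclass
class TissueModel:
    """A voxelized volume conductor: integer labels plus label -> sigma (S/m).

    Every label present in ``labels.values`` must have a conductivity entry;
    sigma must be non-negative and may be zero only for insulator labels
    (exterior air and the lead shaft).
    """

    labels: VoxelGrid
    conductivity: dict[int, float]

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.values.dtype, np.integer):
            raise TypeError("label grid must hold integers")
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.labels.values)
        for lab in present:
            lab = int(lab)
            if lab not in self.conductivity:
                raise ValueError(f"label {lab} has no conductivity entry")
            sigma = self.conductivity[lab]
            if sigma < 0:
                raise ValueError(f"negative conductivity for label {lab}")
            if sigma == 0 and lab not in _INSULATOR_LABELS:
                raise ValueError(
                    f"sigma = 0 only allowed for insulator labels, got label {lab}"
                )

    @property
    def grid(self) -> VoxelGrid:
        return self.labels

    def sigma_volume(self) -> np.ndarray:
        """Per-voxel conductivity array (S/m), same shape as the label grid."""
        labs = self.labels.values
        out = np.zeros(labs.shape, dtype=float)
        for lab, sigma in self.conductivity.items():
            out[labs == lab] = sigma
        return out

    def with_conductivity(self, label: int, sigma: float) -> "TissueModel":
        """A copy with one table entry changed (labels shared, table copied)."""
        table = dict(self.conductivity)
        table[label] = float(sigma)
        return replace(self, conductivity=table)

    def with_labels(self, labels: VoxelGrid) -> "TissueModel":
        return replace(self, labels=labels, conductivity=dict(self.conductivity))
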