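"""Configuration objects and the geometric thresholds used across the package.

Every cutoff that enters a classification decision lives here so that a run
can be reproduced from the serialized config alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

#: Default contact cutoff in Angstroms (minimal heavy-atom distance).
DEFAULT_CUTOFF = 5.0

#: Solvent probe radius for accessible-surface calculations, Angstroms.
DEFAULT_PROBE_RADIUS = 1.4

#: Sphere sample points per atom for Shrake-Rupley SASA.
DEFAULT_SASA_POINTS = 960

#: Default sliding-window width (residues) for sequence Shannon entropy.
DEFAULT_ENTROPY_WINDOW = 9


@dataclass(frozen=True)
class InteractionThresholds:
    """Geometric criteria for the physicochemical contact classifiers.

    All distances in Angstroms, all angles in degrees.

    Attributes
    ----------
    max_group_dist:
        Maximum distance between the representative points of two charge
        groups for an electrostatic label (ion-ion / ion-dipole /
        dipole-dipole).  Salt bridges are often defined at <= 4 A; we keep
        5.0 A to match the default contact cutoff and report the distance.
    d_pipi:
        Maximum ring-centroid distance for a pi-pi stack.
    a_par:
        Maximum angle between ring normals for a parallel pi-pi stack.
    a_perp:
        Half-width of the window around 90 degrees for a T-shaped stack.
    d_x:
        Maximum charge-group-to-ring-centroid distance for cation-pi,
        anion-pi and dipole-pi.
    a_axial:
        Maximum angle between the ring normal and the centroid->group
        vector for the "-pi" labels (the group must sit over the ring face,
        not in its plane).
    hb_da_max:
        Maximum donor--acceptor heavy-atom distance for a hydrogen bond.
    hb_dha_min:
        Minimum D-H...A angle, applied only when the donor hydrogen is
        present in the structure.
    """

    max_group_dist: float = 5.0
    d_pipi: float = 5.5
    a_par: float = 30.0
    a_perp: float = 30.0
    d_x: float = 6.0
    a_axial: float = 45.0
    hb_da_max: float = 3.5
    hb_dha_min: float = 120.0


DEFAULT_THRESHOLDS = InteractionThresholds()


@dataclass
class RunConfig:
    """Fully resolved settings of one analysis run.

    Serialized next to the outputs so that every default that was applied is
    on record.
    """

    cutoff: float = DEFAULT_CUTOFF
    exclude_neighbors: int = 0
    interaction_filter: Optional[str] = None
    include_waters: bool = False
    assembly: Optional[str] = None
    model_index: int = 1
    features_x: list[str] = field(default_factory=list)
    features_y: list[str] = field(default_factory=list)
    altloc_policy: str = "highest_occupancy"
    probe_radius: float = DEFAULT_PROBE_RADIUS
    sasa_points: int = DEFAULT_SASA_POINTS
    entropy_window: int = DEFAULT_ENTROPY_WINDOW
    thresholds: InteractionThresholds = field(default_factory=InteractionThresholds)
    output_dir: str = "."
    seed: int = 0

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"contact cutoff must be positive, got {self.cutoff}")
        if self.exclude_neighbors < 0:
            raise ValueError(
                f"exclude_neighbors must be >= 0, got {self.exclude_neighbors}"
            )
        if self.model_index < 1:
            raise ValueError(f"model index is 1-based, got {self.model_index}")
        if self.entropy_window < 1 or self.entropy_window % 2 == 0:
            raise ValueError(
                f"entropy window must be an odd positive integer, got {self.entropy_window}"
            )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)
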