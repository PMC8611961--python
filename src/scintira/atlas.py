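"""Joint atlas: the 64-joint / 14-area landmark map used for ROI placement.

The atlas positions every joint on one of six planar views (anterior
whole-body plus spot views of both hands, both feet and the posterior
pelvis) and flags the 28-joint subset that enters the DAS28 disease
activity score (bilateral shoulders, elbows, wrists and knees, 10 MCP
joints, both thumb IP joints and the 8 proximal IP joints of digits 2-5).

Landmark geometry is schematic: coordinates are 0-based (row, col) pixel
positions on the synthetic phantom views rendered by
:mod:`scintira.phantom`.  Real scan sets can supply their own atlas via
:func:`JointAtlas.from_csv` / :func:`JointAtlas.from_json`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

#: The 14 joint areas quantified on the phantom.
AREAS = (
    "shoulder",
    "sternoclavicular",
    "elbow",
    "wrist",
    "mcp",
    "thumb_ip",
    "hand_pip",
    "hand_dip",
    "sacroiliac",
    "knee",
    "ankle",
    "tarsal",
    "mtp",
    "foot_ip",
)

#: The six Table-2 reporting areas; "hand_ip" pools thumb IP + proximal IP.
REPORT_AREAS = ("shoulder", "elbow", "wrist", "mcp", "hand_ip", "knee")

VIEWS = (
    "wholebody_anterior",
    "hand_left",
    "hand_right",
    "foot_left",
    "foot_right",
    "pelvis_posterior",
)

#: Default pixel grid of each phantom view (rows, cols).
VIEW_SHAPES = {
    "wholebody_anterior": (220, 80),
    "hand_left": (96, 96),
    "hand_right": (96, 96),
    "foot_left": (96, 96),
    "foot_right": (96, 96),
    "pelvis_posterior": (96, 96),
}

#: Default pixel size per view in mm (whole-body views use a coarser grid).
VIEW_PIXEL_MM = {
    "wholebody_anterior": 6.0,
    "hand_left": 2.4,
    "hand_right": 2.4,
    "foot_left": 2.4,
    "foot_right": 2.4,
    "pelvis_posterior": 2.4,
}


@dataclass(frozen=True)
class JointDefinition:
    """One joint: landmark pixel, ROI radius and DAS28 membership."""

    joint_id: str
    area: str
    side: str  # "left" | "right" | "midline"
    view: str
    row: int
    col: int
    roi_radius: int
    das28_member: bool

    def __post_init__(self):
        if self.roi_radius <= 0:
            raise ConfigurationError(f"roi_radius must be > 0 for {self.joint_id}")
        if self.row < 0 or self.col < 0:
            raise ConfigurationError(
                f"landmark coordinates must be non-negative for {self.joint_id}"
            )
        if self.area not in AREAS:
            raise ConfigurationError(f"unknown area {self.area!r} for {self.joint_id}")
        if self.view not in VIEWS:
            raise ConfigurationError(f"unknown view {self.view!r} for {self.joint_id}")


@dataclass
class JointAtlas:
    """Collection of 64 joint definitions plus auxiliary landmarks.

    ``aux_landmarks`` holds non-joint anatomical anchors (the hip points
    used to place the mid-femoral reference region) as
    ``name -> (view, row, col)``.
    """

    joints: list[JointDefinition]
    version: str = "phantom-1"
    aux_landmarks: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {j.joint_id: j for j in self.joints}
        if len(self._by_id) != len(self.joints):
            raise ConfigurationError("duplicate joint_id in atlas")

    def __len__(self) -> int:
        return len(self.joints)

    def __getitem__(self, joint_id: str) -> JointDefinition:
        return self._by_id[joint_id]

    def __contains__(self, joint_id: str) -> bool:
        return joint_id in self._by_id

    @property
    def joint_ids(self) -> list[str]:
        return [j.joint_id for j in self.joints]

    def das28_joints(self) -> list[JointDefinition]:
        return [j for j in self.joints if j.das28_member]

    def joints_in_area(self, area: str) -> list[JointDefinition]:
        return [j for j in self.joints if j.area == area]

    def joints_in_view(self, view: str) -> list[JointDefinition]:
        return [j for j in self.joints if j.view == view]

    def report_area_of(self, joint_id: str) -> str | None:
        """Map a joint to its six-area reporting group (None if outside)."""
        area = self._by_id[joint_id].area
        if area in ("thumb_ip", "hand_pip"):
            return "hand_ip"
        if area in ("shoulder", "elbow", "wrist", "mcp", "knee"):
            return area
        return None

    def partner_of(self, joint_id: str) -> str | None:
        """Contralateral partner id for bilateral joints, else None."""
        j = self._by_id[joint_id]
        if j.side == "left":
            other = joint_id.replace("_left", "_right")
        elif j.side == "right":
            other = joint_id.replace("_right", "_left")
        else:
            return None
        return other if other in self._by_id else None

    def validate(self, view_shapes: dict[str, tuple[int, int]] | None = None) -> None:
        """Check structural invariants; raise ConfigurationError on failure."""
        if len(self.joints) != 64:
            raise ConfigurationError(f"atlas must contain 64 joints, got {len(self.joints)}")
        areas = {j.area for j in self.joints}
        if areas != set(AREAS):
            raise ConfigurationError(f"atlas must cover the 14 areas, got {sorted(areas)}")
        das28 = self.das28_joints()
        if len(das28) != 28:
            raise ConfigurationError(f"DAS28 subset must have 28 joints, got {len(das28)}")
        from collections import Counter

        das_areas = Counter(j.area for j in das28)
        expected = {
            "shoulder": 2,
            "elbow": 2,
            "wrist": 2,
            "knee": 2,
            "mcp": 10,
            "thumb_ip": 2,
            "hand_pip": 8,
        }
        if dict(das_areas) != expected:
            raise ConfigurationError(f"DAS28 area composition wrong: {dict(das_areas)}")
        for j in self.joints:
            if j.side in ("left", "right") and self.partner_of(j.joint_id) is None:
                raise ConfigurationError(f"bilateral joint {j.joint_id} has no partner")
        if view_shapes:
            for j in self.joints:
                nrow, ncol = view_shapes[j.view]
                if not (0 <= j.row < nrow and 0 <= j.col < ncol):
                    raise ConfigurationError(
                        f"landmark of {j.joint_id} outside view {j.view}"
                    )

    # ------------------------------------------------------------------ IO
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(j) for j in self.joints])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, version: str = "custom",
                   aux_landmarks: dict | None = None) -> "JointAtlas":
        joints = [
            JointDefinition(
                joint_id=str(r.joint_id),
                area=str(r.area),
                side=str(r.side),
                view=str(r.view),
                row=int(r.row),
                col=int(r.col),
                roi_radius=int(r.roi_radius),
                das28_member=bool(r.das28_member),
            )
            for r in df.itertuples()
        ]
        return cls(joints=joints, version=version, aux_landmarks=aux_landmarks or {})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "JointAtlas":
        return cls.from_frame(pd.read_csv(path), **kw)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "joints": [asdict(j) for j in self.joints],
            "aux_landmarks": {k: list(v) for k, v in self.aux_landmarks.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "JointAtlas":
        payload = json.loads(Path(path).read_text())
        joints = [JointDefinition(**j) for j in payload["joints"]]
        aux = {k: (v[0], int(v[1]), int(v[2]))
               for k, v in payload.get("aux_landmarks", {}).items()}
        return cls(joints=joints, version=payload.get("version", "custom"),
                   aux_landmarks=aux)


def _hand_joints(side: str) -> list[JointDefinition]:
    view = f"hand_{side}"
    r = 4
    out = [JointDefinition(f"wrist_{side}", "wrist", side, view, 80, 48, r, True)]
    # digit 1 (thumb) ray sits medially; digits 2-5 fan across the view
    out.append(JointDefinition(f"mcp1_{side}", "mcp", side, view, 62, 12, r, True))
    for digit, col in zip((2, 3, 4, 5), (28, 46, 64, 82)):
        out.append(JointDefinition(f"mcp{digit}_{side}", "mcp", side, view, 52, col, r, True))
    out.append(JointDefinition(f"thumb_ip_{side}", "thumb_ip", side, view, 44, 10, r, True))
    for digit, col in zip((2, 3, 4, 5), (28, 46, 64, 82)):
        out.append(
            JointDefinition(f"hand_pip{digit}_{side}", "hand_pip", side, view, 30, col, r, True)
        )
    for digit, col in zip((2, 3, 4, 5), (28, 46, 64, 82)):
        out.append(
            JointDefinition(f"hand_dip{digit}_{side}", "hand_dip", side, view, 12, col, r, False)
        )
    return out


def _foot_joints(side: str) -> list[JointDefinition]:
    view = f"foot_{side}"
    r = 4
    out = [
        JointDefinition(f"ankle_{side}", "ankle", side, view, 82, 48, r, False),
        JointDefinition(f"tarsal_{side}", "tarsal", side, view, 60, 48, r, False),
    ]
    for digit, col in zip((1, 2, 3, 4, 5), (10, 28, 46, 64, 82)):
        out.append(JointDefinition(f"mtp{digit}_{side}", "mtp", side, view, 36, col, r, False))
    for digit, col in zip((1, 2, 3, 4, 5), (10, 28, 46, 64, 82)):
        out.append(
            JointDefinition(f"foot_ip{digit}_{side}", "foot_ip", side, view, 14, col, r, False)
        )
    return out


def default_atlas() -> JointAtlas:
    """Build the schematic 64-joint phantom atlas.

    Whole-body joints use a 3-px ROI radius (coarser pixel grid), spot-view
    joints 4 px.  Landmarks are spaced so that the centroid-refinement
    search windows (2x radius) of neighbouring joints do not overlap.
    """
    wb = "wholebody_anterior"
    joints = [
        JointDefinition("shoulder_right", "shoulder", "right", wb, 40, 16, 3, True),
        JointDefinition("shoulder_left", "shoulder", "left", wb, 40, 64, 3, True),
        JointDefinition("sternoclavicular_right", "sternoclavicular", "right", wb, 44, 33, 3, False),
        JointDefinition("sternoclavicular_left", "sternoclavicular", "left", wb, 44, 47, 3, False),
        JointDefinition("elbow_right", "elbow", "right", wb, 78, 9, 3, True),
        JointDefinition("elbow_left", "elbow", "left", wb, 78, 71, 3, True),
        JointDefinition("knee_right", "knee", "right", wb, 150, 28, 3, True),
        JointDefinition("knee_left", "knee", "left", wb, 150, 52, 3, True),
        JointDefinition("sacroiliac_right", "sacroiliac", "right", "pelvis_posterior", 40, 30, 4, False),
        JointDefinition("sacroiliac_left", "sacroiliac", "left", "pelvis_posterior", 40, 66, 4, False),
    ]
    for side in ("left", "right"):
        joints.extend(_hand_joints(side))
        joints.extend(_foot_joints(side))
    aux = {
        "hip_right": (wb, 104, 28),
        "hip_left": (wb, 104, 52),
    }
    atlas = JointAtlas(joints=joints, version="phantom-1", aux_landmarks=aux)
    atlas.validate(VIEW_SHAPES)
    return atlas
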