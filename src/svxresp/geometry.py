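"""Common voxel-grid description shared by all co-registered volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError


@dataclass(frozen=True)
class ImageGeometry:
    """Shape and physical spacing of one 3D voxel grid.

    All channels, masks and label volumes of a case live on a single grid
    (inputs are assumed rigidly co-registered). Spacing is in mm per axis
    and may be anisotropic (e.g. 1.75 x 1.75 x 4 mm DSC acquisitions).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValidationError("geometry needs 3 shape and 3 spacing entries")
        if any(s < 8 for s in shape):
            raise ValidationError(f"all shape entries must be >= 8, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValidationError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        """NIfTI-style affine with spacing on the diagonal."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff

    def check_volume(self, volume: np.ndarray, name: str = "volume") -> None:
        if tuple(volume.shape[:3]) != self.shape:
            raise GeometryError(
                f"{name} has shape {tuple(volume.shape[:3])}, expected {self.shape}"
            )


def require_same_geometry(*volumes: np.ndarray) -> tuple[int, int, int]:
    """Assert that all volumes share one 3D shape; return it."""
    shapes = {tuple(v.shape[:3]) for v in volumes}
    if len(shapes) != 1:
        raise GeometryError(f"volumes are on different grids: {sorted(shapes)}")
    return shapes.pop()
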