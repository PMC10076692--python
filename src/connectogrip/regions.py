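"""The 20-region sensorimotor parcellation used throughout the pipeline.

Regions are stored in a lesion-relative ("canonical") frame: bilateral
cortical and subcortical regions carry an ``_ipsi`` / ``_contra`` suffix
(ipsilesional = same hemisphere as the stroke lesion), while the four
brainstem tract regions (corticospinal tract, CST, and corticoreticular
pathway, CRP, each at medulla and midbrain level) are midline and
unlateralized.  Input files use anatomical left/right names plus a
per-participant lesion side; :func:`anatomical_to_canonical` performs the
remapping so that "ipsilesional precentral" is one variable across a cohort
with mixed lesion sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HEMISPHERES = ("ipsilesional", "contralesional", "midline")
REGION_CLASSES = ("cortical", "subcortical", "brainstem_CST", "brainstem_CRP")


@dataclass(frozen=True)
class RegionInfo:
    """One node of the sensorimotor network."""

    name: str
    hemisphere: str  # one of HEMISPHERES
    region_class: str  # one of REGION_CLASSES
    volume_mm3: float
    centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r} for region {self.name!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r} for region {self.name!r}")
        if not self.volume_mm3 > 0:
            raise ValueError(f"region {self.name!r} must have positive volume, got {self.volume_mm3}")


# (base name, class, ipsilesional volume mm^3, |x| y z centroid, MNI-like)
_BILATERAL = (
    ("Precentral", "cortical", 12000.0, (38.0, -12.0, 50.0)),
    ("Rolandic", "cortical", 6000.0, (48.0, -8.0, 18.0)),
    ("Postcentral", "cortical", 11000.0, (40.0, -24.0, 52.0)),
    ("SMA", "cortical", 9000.0, (6.0, -2.0, 58.0)),
    ("Putamen", "subcortical", 4500.0, (26.0, 2.0, 2.0)),
    ("Caudate", "subcortical", 4000.0, (12.0, 10.0, 10.0)),
    ("Pallidum", "subcortical", 1500.0, (20.0, -2.0, 0.0)),
    ("Thalamus", "subcortical", 7500.0, (11.0, -19.0, 8.0)),
)

_BRAINSTEM = (
    ("CST_medulla", "brainstem_CST", 400.0, (0.0, -36.0, -46.0)),
    ("CST_midbrain", "brainstem_CST", 450.0, (0.0, -20.0, -16.0)),
    ("CRP_medulla", "brainstem_CRP", 300.0, (0.0, -40.0, -50.0)),
    ("CRP_midbrain", "brainstem_CRP", 350.0, (0.0, -26.0, -20.0)),
)

# Homologues share a volume: the lesion-relative (ipsi/contra) frame then has
# side-independent volumes, so left- and right-lesion participants see the
# same correction denominators.
_CONTRA_VOLUME_FACTOR = 1.0


def default_regions() -> list[RegionInfo]:
    """The canonical 20-region sensorimotor set (16 bilateral + 4 brainstem)."""
    regions: list[RegionInfo] = []
    for base, cls, vol, (x, y, z) in _BILATERAL:
        regions.append(RegionInfo(f"{base}_ipsi", "ipsilesional", cls, vol, (-x, y, z)))
        regions.append(
            RegionInfo(f"{base}_contra", "contralesional", cls, vol * _CONTRA_VOLUME_FACTOR, (x, y, z))
        )
    for base, cls, vol, cen in _BRAINSTEM:
        regions.append(RegionInfo(base, "midline", cls, vol, cen))
    return regions


def region_names(regions: list[RegionInfo] | None = None) -> list[str]:
    return [r.name for r in (regions if regions is not None else default_regions())]


def volumes_series(regions: list[RegionInfo]) -> pd.Series:
    return pd.Series({r.name: r.volume_mm3 for r in regions}, name="volume_mm3")


def default_distances(regions: list[RegionInfo] | None = None) -> pd.DataFrame:
    """Symmetric Euclidean centroid distances (mm), small floor off-diagonal."""
    if regions is None:
        regions = default_regions()
    pts = np.asarray([r.centroid for r in regions], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    names = [r.name for r in regions]
    off = ~np.eye(len(names), dtype=bool)
    d[off] = np.maximum(d[off], 1.0)  # distinct regions are never co-located
    return pd.DataFrame(d, index=names, columns=names)


def anatomical_name(canonical: str, lesion_side: str) -> str:
    """Map a canonical (lesion-relative) region name to anatomical L/R."""
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be 'left' or 'right', got {lesion_side!r}")
    if canonical.endswith("_ipsi"):
        side = "L" if lesion_side == "left" else "R"
        return canonical[: -len("_ipsi")] + f"_{side}"
    if canonical.endswith("_contra"):
        side = "R" if lesion_side == "left" else "L"
        return canonical[: -len("_contra")] + f"_{side}"
    return canonical  # midline / brainstem


def canonical_name(anatomical: str, lesion_side: str) -> str:
    """Inverse of :func:`anatomical_name`."""
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be 'left' or 'right', got {lesion_side!r}")
    if anatomical.endswith("_L"):
        rel = "ipsi" if lesion_side == "left" else "contra"
        return anatomical[:-2] + f"_{rel}"
    if anatomical.endswith("_R"):
        rel = "contra" if lesion_side == "left" else "ipsi"
        return anatomical[:-2] + f"_{rel}"
    return anatomical


def anatomical_to_canonical(matrix: pd.DataFrame, lesion_side: str) -> pd.DataFrame:
    """Rename a square matrix from anatomical L/R names to the canonical frame."""
    mapping = {name: canonical_name(name, lesion_side) for name in matrix.index}
    out = matrix.rename(index=mapping, columns=mapping)
    return out


def default_anatomical_table(regions: list[RegionInfo] | None = None) -> pd.DataFrame:
    """Region metadata in anatomical (left/right) naming, as stored on disk."""
    if regions is None:
        regions = default_regions()
    rows = []
    for r in regions:
        if r.hemisphere == "midline":
            rows.append((r.name, "midline", r.region_class, r.volume_mm3))
        else:
            # write with the left-lesion mapping; volumes are side-independent
            rows.append((anatomical_name(r.name, "left"), "L" if r.hemisphere == "ipsilesional" else "R",
                         r.region_class, r.volume_mm3))
    return pd.DataFrame(rows, columns=["name", "left_right", "class", "volume_mm3"])
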