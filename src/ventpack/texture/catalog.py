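"""The versioned 496-feature catalog.

Per subject the catalog combines, in a fixed deterministic order:

* 94 features on the original gas image inside the ventilated ROI
  (19 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM);
* the same 94 on each of the four stationary-wavelet subbands (376);
* 14 shape descriptors of the ROI;
* 12 custom ventilation-defect summaries derived from VDP and the
  sphere-packing cluster metrics.

Names are ``<filter>_<family>_<feature>`` with filters ``original``,
``wavelet-LL`` .. ``wavelet-HH``, plus ``shape_*`` and ``custom_*``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..core import Mask3D, Volume3D
from ..spherepack import ClusterMetrics, discrete_ball_offsets
from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .matrices import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .shape import SHAPE_NAMES, shape_features
from .wavelet import SUBBAND_NAMES, wavelet_subbands

__all__ = [
    "CATALOG_VERSION",
    "CUSTOM_NAMES",
    "TextureConfig",
    "FeatureVector",
    "catalog_feature_names",
    "catalog_manifest",
    "extract_catalog",
]

CATALOG_VERSION = "1.0"

CUSTOM_NAMES = (
    "VDP_percent",
    "VDCP_percent",
    "CDD1",
    "ClusterSlope",
    "SphereCountTotal",
    "SphereCountLarge",
    "MaxSphereDiameter_vox",
    "MeanSphereDiameter_vox",
    "MedianSphereDiameter_vox",
    "LargeSphereVolumeFraction",
    "ResidualVolumeFraction",
    "DefectVolume_ml",
)

_FILTERS = ("original",) + tuple(f"wavelet-{b}" for b in SUBBAND_NAMES)
_FAMILIES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("gldm", GLDM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)


@dataclass(frozen=True)
class TextureConfig:
    """Extraction parameters: gray levels, wavelet family, GLDM threshold."""

    bin_count: int = 32
    wavelet: str = "coif1"
    gldm_alpha: float = 0.0


@dataclass(frozen=True)
class FeatureVector:
    """Ordered named feature map for one subject."""

    values: dict[str, float]
    catalog_version: str = CATALOG_VERSION

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def names(self) -> list[str]:
        return list(self.values)


def catalog_feature_names() -> list[str]:
    """The catalog's feature names in extraction order (length 496)."""
    names: list[str] = []
    for filt in _FILTERS:
        for family, feats in _FAMILIES:
            names.extend(f"{filt}_{family}_{f}" for f in feats)
    names.extend(f"shape_{f}" for f in SHAPE_NAMES)
    names.extend(f"custom_{f}" for f in CUSTOM_NAMES)
    return names


def catalog_manifest() -> list[dict[str, str]]:
    """Machine-readable catalog manifest: name, filter and family."""
    manifest = []
    for name in catalog_feature_names():
        if name.startswith("shape_"):
            filt, family, feat = "none", "shape", name[len("shape_") :]
        elif name.startswith("custom_"):
            filt, family, feat = "none", "custom", name[len("custom_") :]
        else:
            filt, rest = name.split("_", 1)
            family, feat = rest.split("_", 1)
        manifest.append(
            {
                "name": name,
                "filter": filt,
                "family": family,
                "feature": feat,
                "catalog_version": CATALOG_VERSION,
            }
        )
    return manifest


def _image_features(arr: np.ndarray, roi_mask: np.ndarray, cfg: TextureConfig,
                    voxel_volume_mm3: float) -> dict[str, float]:
    out = dict(
        firstorder=firstorder_features(arr, roi_mask, cfg.bin_count, voxel_volume_mm3)
    )
    d = discretize(arr, roi_mask, cfg.bin_count)
    out["glcm"] = glcm_features(d)
    out["glrlm"] = glrlm_features(d)
    out["glszm"] = glszm_features(d)
    out["gldm"] = gldm_features(d, cfg.gldm_alpha)
    out["ngtdm"] = ngtdm_features(d)
    return {
        f"{family}_{k}": v
        for family, feats in out.items()
        for k, v in feats.items()
    }


def _custom_features(
    metrics: Optional[ClusterMetrics], vdp: Optional[float], voxel_volume_mm3: float
) -> dict[str, float]:
    nan = float("nan")
    vals = {f"custom_{n}": nan for n in CUSTOM_NAMES}
    if vdp is not None:
        vals["custom_VDP_percent"] = float(vdp)
    if metrics is None:
        warnings.warn("defect cluster metrics missing; custom features set to NaN")
        return vals
    hist = metrics.size_histogram
    total = sum(hist.values())
    covered = sum(len(discrete_ball_offsets(d)) * c for d, c in hist.items() if d > 1)
    region = covered + hist.get(1, 0)
    diam_counts = sorted(hist.items())
    diam_expanded = np.repeat(
        [d for d, _ in diam_counts], [c for _, c in diam_counts]
    ) if total else np.array([])

    vals["custom_VDCP_percent"] = metrics.vdcp_percent
    vals["custom_CDD1"] = float(metrics.cdd1)
    vals["custom_ClusterSlope"] = metrics.cluster_slope
    vals["custom_SphereCountTotal"] = float(total)
    vals["custom_SphereCountLarge"] = float(total - hist.get(1, 0))
    vals["custom_MaxSphereDiameter_vox"] = float(max(hist)) if hist else 0.0
    vals["custom_MeanSphereDiameter_vox"] = float(diam_expanded.mean()) if total else 0.0
    vals["custom_MedianSphereDiameter_vox"] = float(np.median(diam_expanded)) if total else 0.0
    vals["custom_LargeSphereVolumeFraction"] = covered / region if region else 0.0
    vals["custom_ResidualVolumeFraction"] = hist.get(1, 0) / region if region else 0.0
    vals["custom_DefectVolume_ml"] = region * voxel_volume_mm3 / 1000.0
    return vals


def extract_catalog(
    he3: Volume3D,
    roi: Mask3D,
    defect_metrics: Optional[ClusterMetrics] = None,
    vdp: Optional[float] = None,
    config: TextureConfig | None = None,
) -> FeatureVector:
    """Extract the full 496-entry feature vector for one subject.

    Matrix and first-order families are computed on the original gas image
    and on its four wavelet subbands inside ``roi``; shape features on the
    ROI mask; custom defect summaries from ``vdp`` and ``defect_metrics``
    (NaN sentinels with a warning when the metrics are missing).
    Extraction is deterministic: identical inputs give identical vectors.
    """
    cfg = config or TextureConfig()
    vv = he3.voxel_volume_mm3
    roi_mask = roi.voxels
    values: dict[str, float] = {}

    per_image = {"original": he3.voxels}
    bands = wavelet_subbands(he3, cfg.wavelet)
    for b in SUBBAND_NAMES:
        per_image[f"wavelet-{b}"] = bands[b]

    for filt in _FILTERS:
        feats = _image_features(per_image[filt], roi_mask, cfg, vv)
        values.update({f"{filt}_{k}": v for k, v in feats.items()})

    values.update({f"shape_{k}": v for k, v in shape_features(roi).items()})
    values.update(_custom_features(defect_metrics, vdp, vv))

    ordered = {n: values[n] for n in catalog_feature_names()}
    return FeatureVector(values=ordered)
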