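"""DTI-ALPS index computation.

The index quantifies perivascular diffusivity along the medullary veins
(left-right, x) relative to the diffusivities perpendicular to both the
perivascular direction and the dominant fibre direction in the
projection (head-foot, z) and association (anterior-posterior, y)
regions:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

computed per hemisphere; the bilateral index is the average of the left
and right indices.  An index near 1.0 indicates no preferential
perivascular diffusion (impairment floor); healthy white matter sits
around 1.3.

Manual placement inspection is replaced by an automated QC proxy: each
ROI must show sufficient mean FA, a sufficient fraction of principal
eigenvectors within a cone around the expected fibre axis, and a
minimum voxel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rois import EXPECTED_AXIS, ROISet, SphereROI, rasterize_sphere
from .tensor import fa_map, principal_eigenvectors
from .volumes import ScalarVolume, TensorVolume


@dataclass(frozen=True)
class QCThresholds:
    """Automated placement-QC thresholds (proxy for visual inspection)."""

    fa_min: float = 0.15
    align_min: float = 0.5       # fraction of voxels within the axis cone
    cone_deg: float = 30.0       # half-angle of the acceptance cone
    count_min: int = 10


@dataclass
class QCReport:
    per_roi: dict[str, dict]     # label -> {mean_fa, align_fraction, n_voxels}
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"per_roi": self.per_roi, "passed": self.passed, "reasons": self.reasons}


@dataclass
class ALPSResult:
    """Per-hemisphere axis diffusivities and the three ALPS indices."""

    diffusivities: dict[str, dict[str, float]]  # hemi -> {dxx_proj, dxx_assoc, dyy_proj, dzz_assoc}
    alps_left: float
    alps_right: float
    alps_mean: float
    qc: QCReport
    voxel_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "alps_left": self.alps_left,
            "alps_right": self.alps_right,
            "alps_mean": self.alps_mean,
            "diffusivities": self.diffusivities,
            "voxel_counts": self.voxel_counts,
            "qc": self.qc.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


class ALPSComputationError(ValueError):
    pass


def extract_axis_diffusivities(t: TensorVolume, mask: np.ndarray):
    """Mean (Dxx, Dyy, Dzz) over in-mask voxels with finite diagonals.

    Non-finite diagonal entries exclude the voxel from the mean; if no
    voxel survives, raises ALPSComputationError.
    """
    if mask.shape != t.shape:
        raise ValueError("mask and tensor volume must share a grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    diag = t.diagonal()[mask]                 # (V, 3)
    finite = np.isfinite(diag).all(axis=1)
    if not finite.any():
        raise ALPSComputationError("all ROI voxels have non-finite diffusivities")
    m = diag[finite].mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2]), int(finite.sum())


def qc_placement(fa: ScalarVolume, t: TensorVolume, rois: ROISet,
                 thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Check each ROI sits in coherent fibre tissue of the expected axis."""
    if fa.values.shape != t.shape:
        raise ValueError("FA map and tensor volume must share a grid")
    v1 = principal_eigenvectors(t)
    cos_min = np.cos(np.deg2rad(thresholds.cone_deg))
    per_roi: dict[str, dict] = {}
    reasons: list[str] = []
    for roi in rois:
        mask = rasterize_sphere(roi, t.affine, t.shape)
        n = int(mask.sum())
        mean_fa = float(fa.values[mask].mean())
        axis = EXPECTED_AXIS[roi.fiber_type]
        align = float((np.abs(v1[mask][:, axis]) >= cos_min).mean())
        per_roi[roi.label] = {"mean_fa": mean_fa, "align_fraction": align, "n_voxels": n}
        if n < thresholds.count_min:
            reasons.append(f"{roi.label}: only {n} voxels (< {thresholds.count_min})")
        if mean_fa < thresholds.fa_min:
            reasons.append(f"{roi.label}: low FA {mean_fa:.3f} (< {thresholds.fa_min})")
        if align < thresholds.align_min:
            reasons.append(
                f"{roi.label}: principal-axis misalignment, fraction {align:.2f} "
                f"within {thresholds.cone_deg:.0f} deg cone (< {thresholds.align_min})"
            )
    return QCReport(per_roi=per_roi, passed=not reasons, reasons=reasons)


def compute_alps(t: TensorVolume, rois: ROISet,
                 thresholds: QCThresholds = QCThresholds(),
                 fa: ScalarVolume | None = None) -> ALPSResult:
    """Compute left, right and bilateral ALPS indices with placement QC.

    A failed QC does not suppress the indices; the result carries the
    fail status so callers can exclude the subject, mirroring exclusion
    after visual inspection.
    """
    diffs: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    indices: dict[str, float] = {}
    for hemi in ("left", "right"):
        proj = rois[f"projection_{hemi}"]
        assoc = rois[f"association_{hemi}"]
        pmask = rasterize_sphere(proj, t.affine, t.shape)
        amask = rasterize_sphere(assoc, t.affine, t.shape)
        dxx_p, dyy_p, _, n_p = extract_axis_diffusivities(t, pmask)
        dxx_a, _, dzz_a, n_a = extract_axis_diffusivities(t, amask)
        counts[proj.label] = n_p
        counts[assoc.label] = n_a
        diffs[hemi] = {"dxx_proj": dxx_p, "dxx_assoc": dxx_a,
                       "dyy_proj": dyy_p, "dzz_assoc": dzz_a}
        denom = (dyy_p + dzz_a) / 2.0
        if denom <= 0:
            raise ALPSComputationError(
                f"{hemi} hemisphere: non-positive denominator mean(Dyy_proj, Dzz_assoc) = {denom:g}"
            )
        indices[hemi] = ((dxx_p + dxx_a) / 2.0) / denom

    if fa is None:
        fa = fa_map(t)
    qc = qc_placement(fa, t, rois, thresholds)
    return ALPSResult(
        diffusivities=diffs,
        alps_left=indices["left"],
        alps_right=indices["right"],
        alps_mean=(indices["left"] + indices["right"]) / 2.0,
        qc=qc,
        voxel_counts=counts,
    )
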