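"""Rule-based scan-range decision: flags A-D, final verdict, length, dose.

The decision stage consumes a CT volume plus its two landmark masks and
reproduces a radiologist's scan-range audit for lung-cancer-screening
chest LDCT:

superior side
    If the thyroid cartilage is localized, the slices superior to its top
    decide the superior overscan (strictly more than ``tau_superior`` mm
    of coverage above the cartilage top).  When the cartilage is not
    detected, 64x64-pixel ROI patches around the airway on the ten most
    superior slices are examined instead: visible pyriform sinuses mean
    the scan reached the hypopharynx (overscan); failing that, a run of
    closed-lumen ("closed vocal cord") slices longer than ``tau_superior``
    means overscan; lung parenchyma in the patches with neither cue means
    the scan started inside the chest (superior underscan).

inferior side
    Strictly more than ``tau_inferior`` mm of scan beyond the most
    inferior kidney slice is an inferior overscan.  With no kidney found,
    spine-anchored patches on the ten most inferior slices are used: lung
    parenchyma in the last patch means the scan stopped inside the chest
    (inferior underscan); otherwise the case is acceptable, which also
    covers true kidney absence.

The four Boolean identification items (A: superior overscan, B: inferior
overscan, C: superior underscan, D: inferior underscan) default to False
and are only set True by the branch logic; the final overscan/underscan
verdicts are OR gates over them.  The overscan length is the number of
slices determined as overscan times the reconstructed slice thickness,
and the excessive effective dose is CTDI_vol x length x k with the
region-specific conversion factors k (neck 0.0059, abdomen 0.015
mSv/(mGy cm)).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .segmentation import LandmarkMask, segment_landmark
from .volume import CTVolume

__all__ = [
    "Thresholds",
    "RangeFlags",
    "PatchSeries",
    "DoseEstimate",
    "OverscanReport",
    "locate_airway",
    "locate_spine",
    "extract_patches",
    "detect_pyriform_sinus",
    "closed_cord_length",
    "contains_lung_parenchyma",
    "superior_branch",
    "inferior_branch",
    "final_decision",
    "excessive_dose",
    "decide_volume",
]


@dataclass(frozen=True)
class Thresholds:
    """All tunable decision parameters, with the audit defaults.

    ``tau_superior``/``tau_inferior`` are compared strictly (a case exactly
    at the threshold is acceptable); the parenchyma area fraction uses >=.
    """

    tau_superior: float = 9.0  # mm
    tau_inferior: float = 3.0  # mm
    airway_window: tuple[float, float] = (-1000.0, -900.0)  # HU, inclusive
    spine_hu: float = 150.0  # HU, strict >
    parenchyma_window: tuple[float, float] = (-950.0, -650.0)  # HU
    parenchyma_fraction: float = 0.20  # of patch area, >=
    min_component_px: int = 10  # 2-D air/bone component floor
    min_landmark_voxels: int = 5  # per-slice mask voxels for "present"
    pyriform_lateral_px: int = 6  # minimal lateral offset of sinus air
    patch_size: int = 64
    n_patch_slices: int = 10
    k_superior: float = 0.0059  # mSv / (mGy cm), neck
    k_inferior: float = 0.015  # mSv / (mGy cm), abdomen

    def __post_init__(self):
        if self.tau_superior < 0 or self.tau_inferior < 0:
            raise ValueError("tau thresholds must be >= 0")


@dataclass
class RangeFlags:
    """Identification information A-D; all default False."""

    info_a: bool = False  # superior overscan
    info_b: bool = False  # inferior overscan
    info_c: bool = False  # superior underscan
    info_d: bool = False  # inferior underscan

    def validate(self) -> None:
        if self.info_a and self.info_c:
            raise ValueError("superior over- and underscan cannot both be set")
        if self.info_b and self.info_d:
            raise ValueError("inferior over- and underscan cannot both be set")

    @property
    def overscan(self) -> bool:
        return self.info_a or self.info_b

    @property
    def underscan(self) -> bool:
        return self.info_c or self.info_d


@dataclass
class PatchSeries:
    """Up to ten 64x64 HU patches from the extreme slices of one side."""

    patches: list[np.ndarray]
    centers: list[tuple[int, int]]
    slice_indices: list[int]
    side: str

    def __post_init__(self):
        if self.side not in ("superior", "inferior"):
            raise ValueError("side must be 'superior' or 'inferior'")

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class DoseEstimate:
    superior_mSv: float
    inferior_mSv: float

    @property
    def total_mSv(self) -> float:
        return self.superior_mSv + self.inferior_mSv


@dataclass
class OverscanReport:
    """Final per-series decision with lengths, dose and alert status."""

    series_id: str
    flags: RangeFlags
    superior_count: int
    inferior_count: int
    slice_thickness: float
    dose: Optional[DoseEstimate]
    status: str  # acceptable | overscan | underscan | mixed
    thresholds: Thresholds

    @property
    def superior_length_mm(self) -> float:
        return self.superior_count * self.slice_thickness

    @property
    def inferior_length_mm(self) -> float:
        return self.inferior_count * self.slice_thickness

    @property
    def total_length_cm(self) -> float:
        return (self.superior_length_mm + self.inferior_length_mm) / 10.0

    @property
    def score_mm(self) -> float:
        """Per-case overscan score: max per-side excess length in mm."""
        return max(self.superior_length_mm, self.inferior_length_mm)

    def to_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "flags": asdict(self.flags),
            "superior_count": self.superior_count,
            "inferior_count": self.inferior_count,
            "superior_length_mm": self.superior_length_mm,
            "inferior_length_mm": self.inferior_length_mm,
            "length_cm": self.total_length_cm,
            "score_mm": self.score_mm,
            "dose_mSv": None
            if self.dose is None
            else {
                "superior": self.dose.superior_mSv,
                "inferior": self.dose.inferior_mSv,
                "total": self.dose.total_mSv,
            },
            "status": self.status,
            "thresholds": asdict(self.thresholds),
        }

    def to_row(self) -> dict:
        """Flat CSV row compatible with the stats module."""
        return {
            "series_id": self.series_id,
            "predicted_overscan": int(self.flags.overscan),
            "predicted_underscan": int(self.flags.underscan),
            "score_mm": self.score_mm,
            "superior_length_mm": self.superior_length_mm,
            "inferior_length_mm": self.inferior_length_mm,
            "status": self.status,
            "excess_dose_mSv": "" if self.dose is None else self.dose.total_mSv,
        }


# ---------------------------------------------------------------------------
# anchors and patches
# ---------------------------------------------------------------------------

def _largest_component_centroid(mask2d, min_px, exclude_border):
    lab, n = ndimage.label(mask2d)
    if n == 0:
        return None
    if exclude_border:
        border = np.unique(
            np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        )
        for b in border:
            if b:
                lab[lab == b] = 0
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    if sizes.size == 0 or sizes.max() < min_px:
        return None
    best = int(sizes.argmax())
    return ndimage.center_of_mass(lab == best)


def locate_airway(
    slice_hu: np.ndarray, thresholds: Thresholds = Thresholds()
) -> Optional[tuple[float, float]]:
    """Centroid of the airway lumen on one slice, or None.

    The airway is the largest connected component within the airway HU
    window that does not touch the image border (air outside the body
    always does) and meets the minimal area.
    """
    lo, hi = thresholds.airway_window
    mask = (slice_hu >= lo) & (slice_hu <= hi)
    return _largest_component_centroid(mask, thresholds.min_component_px, True)


def locate_spine(
    slice_hu: np.ndarray, thresholds: Thresholds = Thresholds()
) -> Optional[tuple[float, float]]:
    """Centroid of the vertebral column (largest component strictly above
    the bone threshold), or None."""
    mask = slice_hu > thresholds.spine_hu
    return _largest_component_centroid(mask, thresholds.min_component_px, False)


def _clamp(v: float, lo: int, hi: int) -> int:
    return int(min(max(round(v), lo), hi))


def extract_patches(
    volume: CTVolume,
    side: str,
    anchor_locator: Optional[Callable] = None,
    thresholds: Thresholds = Thresholds(),
) -> PatchSeries:
    """ROI patches from the ten extreme slices of one side.

    Each patch is centered on the anchor found on its own slice; slices
    without an anchor borrow the nearest slice's anchor and fall back to
    the image center.  Centers are clamped so patches stay in bounds
    (images smaller than the patch are padded with air).
    """
    if volume.n_slices < 1:
        raise ValueError("volume has no slices")
    if side == "superior":
        idx = list(range(min(thresholds.n_patch_slices, volume.n_slices)))
        if anchor_locator is None:
            anchor_locator = locate_airway
    elif side == "inferior":
        idx = list(range(max(0, volume.n_slices - thresholds.n_patch_slices), volume.n_slices))
        if anchor_locator is None:
            anchor_locator = locate_spine
    else:
        raise ValueError("side must be 'superior' or 'inferior'")

    anchors: list[Optional[tuple[float, float]]] = [
        anchor_locator(volume.voxels[i], thresholds) for i in idx
    ]
    rows, cols = volume.voxels.shape[1:]
    center_default = (rows / 2.0, cols / 2.0)
    found = [k for k, a in enumerate(anchors) if a is not None]
    resolved = []
    for k in range(len(idx)):
        if anchors[k] is not None:
            resolved.append(anchors[k])
        elif found:
            nearest = min(found, key=lambda j: abs(j - k))
            resolved.append(anchors[nearest])
        else:
            resolved.append(center_default)

    size = thresholds.patch_size
    half = size // 2
    patches, centers = [], []
    for k, i in enumerate(idx):
        img = volume.voxels[i]
        if rows < size or cols < size:
            pad_r, pad_c = max(0, size - rows), max(0, size - cols)
            img = np.pad(
                img,
                ((0, pad_r), (0, pad_c)),
                constant_values=int(thresholds.airway_window[0]),
            )
        r = _clamp(resolved[k][0], half, img.shape[0] - half)
        c = _clamp(resolved[k][1], half, img.shape[1] - half)
        patches.append(img[r - half : r + half, c - half : c + half].copy())
        centers.append((r, c))
    return PatchSeries(patches=patches, centers=centers, slice_indices=idx, side=side)


# ---------------------------------------------------------------------------
# patch-level detectors
# ---------------------------------------------------------------------------

def _air_components(patch, thresholds):
    lo, hi = thresholds.airway_window
    mask = (patch >= lo) & (patch <= hi)
    lab, n = ndimage.label(mask)
    comps = []
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < thresholds.min_component_px:
            continue
        touches = comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any()
        comps.append((ndimage.center_of_mass(comp), int(comp.sum()), touches))
    return comps


def detect_pyriform_sinus(patch: np.ndarray, thresholds: Thresholds = Thresholds()) -> bool:
    """True iff paired sinus-like air recesses flank the patch midline.

    Requires at least one enclosed air component of sufficient area on
    each side of the midline at a minimal lateral offset; a single central
    air component is the airway, not the sinuses, and air reaching the
    patch border is outside the body.
    """
    mid = patch.shape[1] / 2.0
    off = thresholds.pyriform_lateral_px
    left = right = False
    for (r, c), area, touches in _air_components(patch, thresholds):
        if touches:
            continue
        if c <= mid - off:
            left = True
        elif c >= mid + off:
            right = True
    return left and right


def _central_lumen_open(patch, thresholds) -> bool:
    size = patch.shape[0]
    third = size // 3
    sub = patch[third : size - third, third : size - third]
    lo, hi = thresholds.airway_window
    mask = (sub >= lo) & (sub <= hi)
    lab, n = ndimage.label(mask)
    if n == 0:
        return False
    return int(np.bincount(lab.ravel())[1:].max()) >= thresholds.min_component_px


def closed_cord_length(
    patches: PatchSeries,
    slice_thickness: float,
    thresholds: Thresholds = Thresholds(),
) -> float:
    """Length (mm) of the leading run of closed-lumen superior patches.

    A patch counts as "closed" when the central third of the patch holds
    no air component of at least the minimal area — the appearance of
    vocal cords touching each other.
    """
    if patches.side != "superior":
        raise ValueError("closed-cord length is defined on the superior side")
    run = 0
    for patch in patches.patches:
        if _central_lumen_open(patch, thresholds):
            break
        run += 1
    return run * slice_thickness


def contains_lung_parenchyma(
    patch: np.ndarray, thresholds: Thresholds = Thresholds()
) -> bool:
    """True iff the patch's parenchyma-window pixel fraction is >= the
    configured area fraction."""
    lo, hi = thresholds.parenchyma_window
    frac = float(((patch >= lo) & (patch <= hi)).mean())
    return frac >= thresholds.parenchyma_fraction


# ---------------------------------------------------------------------------
# branch logic
# ---------------------------------------------------------------------------

def _closed_run_count(patches, thresholds) -> int:
    run = 0
    for patch in patches.patches:
        if _central_lumen_open(patch, thresholds):
            break
        run += 1
    return run


def superior_branch(
    volume: CTVolume,
    cartilage_mask: LandmarkMask,
    thresholds: Thresholds = Thresholds(),
) -> tuple[RangeFlags, int]:
    """Superior-side rule chain; returns (flag contribution, slice count).

    The reported count includes every slice above the landmark limit —
    the tau allowance is a decision threshold, not subtracted from the
    length.
    """
    if cartilage_mask.mask.shape != volume.voxels.shape:
        raise ValueError("cartilage mask is not aligned to the volume")
    flags = RangeFlags()
    spacing = volume.slice_spacing
    counts = cartilage_mask.slice_counts()
    present = np.where(counts >= thresholds.min_landmark_voxels)[0]
    if present.size:
        count = int(present[0])  # slices superior to the cartilage top
        flags.info_a = count * spacing > thresholds.tau_superior
        return flags, count

    patches = extract_patches(volume, "superior", locate_airway, thresholds)
    pyriform_hits = [k for k, p in enumerate(patches.patches)
                     if detect_pyriform_sinus(p, thresholds)]
    if pyriform_hits:
        flags.info_a = True
        # slices at or above the deepest sinus level are above the cords
        return flags, pyriform_hits[-1] + 1
    closed = _closed_run_count(patches, thresholds)
    if closed * spacing > thresholds.tau_superior:
        flags.info_a = True
        return flags, closed
    if any(contains_lung_parenchyma(p, thresholds) for p in patches.patches):
        flags.info_c = True
        return flags, 0
    return flags, 0


def inferior_branch(
    volume: CTVolume,
    kidney_mask: LandmarkMask,
    thresholds: Thresholds = Thresholds(),
) -> tuple[RangeFlags, int]:
    """Inferior-side rule chain; returns (flag contribution, slice count)."""
    if kidney_mask.mask.shape != volume.voxels.shape:
        raise ValueError("kidney mask is not aligned to the volume")
    flags = RangeFlags()
    spacing = volume.slice_spacing
    counts = kidney_mask.slice_counts()
    present = np.where(counts >= thresholds.min_landmark_voxels)[0]
    if present.size:
        count = int(volume.n_slices - 1 - present[-1])  # beyond the last kidney
        flags.info_b = count * spacing > thresholds.tau_inferior
        return flags, count

    patches = extract_patches(volume, "inferior", locate_spine, thresholds)
    if contains_lung_parenchyma(patches.patches[-1], thresholds):
        flags.info_d = True
    # no kidney and no parenchyma: acceptable (covers true kidney absence)
    return flags, 0


def excessive_dose(
    ctdi_vol: Optional[float],
    superior_length_cm: float,
    inferior_length_cm: float,
    thresholds: Thresholds = Thresholds(),
) -> DoseEstimate:
    """Excessive effective dose, mSv: CTDI_vol x length_cm x k per side."""
    if ctdi_vol is None:
        raise ValueError("excessive dose not computable without CTDI_vol")
    if superior_length_cm < 0 or inferior_length_cm < 0:
        raise ValueError("lengths must be >= 0")
    return DoseEstimate(
        superior_mSv=ctdi_vol * superior_length_cm * thresholds.k_superior,
        inferior_mSv=ctdi_vol * inferior_length_cm * thresholds.k_inferior,
    )


def final_decision(
    flags: RangeFlags,
    superior_count: int,
    inferior_count: int,
    slice_thickness: float,
    ctdi_vol: Optional[float] = None,
    series_id: str = "",
    thresholds: Thresholds = Thresholds(),
) -> OverscanReport:
    """OR-gate verdict, overscan lengths, alert status and dose."""
    flags.validate()
    if superior_count < 0 or inferior_count < 0:
        raise ValueError("slice counts must be >= 0")

    overscan = flags.overscan
    underscan = flags.underscan
    if overscan and underscan:
        status = "mixed"
    elif overscan:
        status = "overscan"
    elif underscan:
        status = "underscan"
    else:
        status = "acceptable"

    dose = None
    if ctdi_vol is not None:
        # dose accrues only on sides decided as overscan
        sup_cm = superior_count * slice_thickness / 10.0 if flags.info_a else 0.0
        inf_cm = inferior_count * slice_thickness / 10.0 if flags.info_b else 0.0
        dose = excessive_dose(ctdi_vol, sup_cm, inf_cm, thresholds)

    return OverscanReport(
        series_id=series_id,
        flags=flags,
        superior_count=superior_count,
        inferior_count=inferior_count,
        slice_thickness=slice_thickness,
        dose=dose,
        status=status,
        thresholds=thresholds,
    )


def decide_volume(
    volume: CTVolume,
    thresholds: Thresholds = Thresholds(),
    backend: str = "classical",
    cartilage_mask: Optional[LandmarkMask] = None,
    kidney_mask: Optional[LandmarkMask] = None,
    models: Optional[dict] = None,
) -> OverscanReport:
    """End-to-end decision for one volume.

    Masks may be supplied directly (e.g. ground-truth masks); otherwise
    they are produced by the requested segmentation backend.
    """
    models = models or {}
    if cartilage_mask is None:
        cartilage_mask = segment_landmark(
            volume, "thyroid_cartilage", backend, models.get("thyroid_cartilage")
        )
    if kidney_mask is None:
        kidney_mask = segment_landmark(volume, "kidney", backend, models.get("kidney"))

    sup_flags, sup_count = superior_branch(volume, cartilage_mask, thresholds)
    inf_flags, inf_count = inferior_branch(volume, kidney_mask, thresholds)
    flags = RangeFlags(
        info_a=sup_flags.info_a,
        info_b=inf_flags.info_b,
        info_c=sup_flags.info_c,
        info_d=inf_flags.info_d,
    )
    return final_decision(
        flags,
        sup_count,
        inf_count,
        volume.slice_spacing,
        ctdi_vol=volume.ctdi_vol,
        series_id=volume.series_id,
        thresholds=thresholds,
    )
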