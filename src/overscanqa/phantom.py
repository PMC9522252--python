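"""Seeded synthetic chest LDCT phantoms with known scan-range ground truth.

Each phantom is a stylized head-to-abdomen axial CT stack containing every
anatomical cue the scan-range decision rules inspect:

* an air-filled airway tube (-1000 HU) running through the neck into the
  chest, optionally closed (soft tissue) over a "closed vocal cord" band;
* paired pyriform-sinus air pockets lateral to the airway just above the
  thyroid cartilage;
* the thyroid cartilage as a high-contrast partial ring around the airway
  (superior landmark);
* lung parenchyma (~-850 HU) over the thoracic extent;
* a vertebral column (>150 HU) on every slice;
* paired kidneys embedded in retroperitoneal fat (inferior landmark).

Scan coverage is controlled by two signed margins: ``superior_margin`` is
the length of scan above the thyroid-cartilage top (>0 means the scan
starts above it) and ``inferior_margin`` the length beyond the kidney
bottom (>0 means the scan continues below it).  Margins are rendered to
whole slices by truncation toward zero — a partial slice cannot be
reconstructed — and the truth labels are a pure function of the realized
margins and the active decision thresholds.

The geometry is a deliberately simple piecewise-constant HU model: no
beam hardening, reconstruction kernels or deformable anatomy.  Additive
Gaussian noise emulates quantum noise; identical seeds give bit-identical
volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .volume import CTVolume, GoldRecord, write_ct_series

__all__ = [
    "Anatomy",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "iter_cohort",
    "generate_cohort",
    "export_cohort",
    "DEFAULT_PREVALENCE",
]

#: overscan prevalence of the default cohort (47 tagged of 210)
DEFAULT_PREVALENCE = 47.0 / 210.0

# HU palette.  Values are chosen so that the literal rule thresholds
# discriminate: air within the airway window [-1000, -900], cartilage and
# spine well above the 150 HU bone threshold, parenchyma ~-850 HU, and
# kidneys (soft tissue) isolated from the body by a fat capsule.
HU_AIR = -1000
HU_BODY = 40
HU_LUNG = -850
HU_FAT = -100
HU_KIDNEY = 35
HU_BONE = 400

_AIR, _BODY, _LUNG, _FAT, _KIDNEY, _SPINE, _CARTILAGE, _AIRWAY, _PYRIFORM = range(9)
_PALETTE = np.array(
    [HU_AIR, HU_BODY, HU_LUNG, HU_FAT, HU_KIDNEY, HU_BONE, HU_BONE, HU_AIR, HU_AIR],
    dtype=np.float32,
)

#: HU ceiling/floor applied after noise; CT numbers saturate at the air floor
HU_CLIP = (-1000, 2000)


@dataclass(frozen=True)
class Anatomy:
    """Organ extents along the scan axis, mm.

    The anatomical z axis points inferior and is anchored at the top of the
    thyroid cartilage (z = 0).  Dimensions are plausible adult defaults and
    are not fitted to any particular population.
    """

    cartilage_span: tuple[float, float] = (0.0, 12.0)
    pyriform_span: tuple[float, float] = (-20.0, -6.0)
    lung_span: tuple[float, float] = (12.0, 252.0)
    kidney_span: tuple[float, float] = (258.0, 358.0)
    airway_bottom: float = 90.0  # carina level; the airway tube ends here

    def __post_init__(self):
        order = [
            self.pyriform_span[0],
            self.pyriform_span[1],
            self.cartilage_span[0],
            self.cartilage_span[1],
            self.kidney_span[0],
            self.kidney_span[1],
        ]
        if sorted(order) != order:
            raise ValueError("anatomy spans must be ordered superior to inferior")
        if self.lung_span[0] >= self.lung_span[1]:
            raise ValueError("lung span must be non-empty")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom acquisition."""

    shape: tuple[int, int] = (128, 128)  # rows, cols
    slice_thickness: float = 1.0  # mm
    pixel_spacing: float = 3.0  # mm, square pixels
    superior_margin: float = 4.0  # mm above cartilage top (signed)
    inferior_margin: float = 0.0  # mm beyond kidney bottom (signed)
    noise_sigma: float = 20.0  # HU; use 60 for an LDCT noise stress test
    anatomy: Anatomy = field(default_factory=Anatomy)
    kidneys_present: bool = True
    cartilage_present: bool = True
    closed_cord_span: Optional[tuple[float, float]] = None  # z band, mm
    ctdi_vol: Optional[float] = 2.4  # mGy
    seed: int = 0
    series_id: str = ""

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.slice_thickness <= 0 or self.pixel_spacing <= 0:
            raise ValueError("geometry must be positive")

    @classmethod
    def from_config(cls, path) -> "PhantomSpec":
        """Read a flat key=value config file (comments with '#')."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs: dict = {}
        for key, val in kv.items():
            if key == "shape":
                r, c = val.split(",")
                kwargs["shape"] = (int(r), int(c))
            elif key in ("kidneys_present", "cartilage_present"):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key == "closed_cord_span":
                a, b = val.split(",")
                kwargs[key] = (float(a), float(b))
            elif key in ("seed",):
                kwargs[key] = int(val)
            elif key == "series_id":
                kwargs[key] = val
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom.

    ``superior_excess_mm``/``inferior_excess_mm`` are the realized signed
    scan margins (whole slices).  Flags follow the stated thresholds:
    superior overscan iff the superior excess exceeds tau_superior, etc.
    """

    masks: dict[str, np.ndarray]
    superior_excess_mm: float
    inferior_excess_mm: float
    superior_overscan: bool
    inferior_overscan: bool
    superior_underscan: bool
    inferior_underscan: bool
    tau_superior: float
    tau_inferior: float

    @property
    def overscan(self) -> bool:
        return self.superior_overscan or self.inferior_overscan

    @property
    def underscan(self) -> bool:
        return self.superior_underscan or self.inferior_underscan


def _truth_flags(
    sup_mm: float, inf_mm: float, anatomy: Anatomy, tau_sup: float, tau_inf: float
) -> tuple[bool, bool, bool, bool]:
    cart_len = anatomy.cartilage_span[1] - anatomy.cartilage_span[0]
    sup_over = sup_mm > tau_sup
    sup_under = sup_mm < -cart_len  # scan top below the cartilage bottom
    inf_over = inf_mm > tau_inf
    # scan bottom above the lung base (lung coverage cut short)
    inf_under = inf_mm < anatomy.lung_span[1] - anatomy.kidney_span[1]
    return sup_over, inf_over, sup_under, inf_under


def _disk(rows, cols, center, radius):
    rr, cc = np.ogrid[:rows, :cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse(rows, cols, center, semi):
    rr, cc = np.ogrid[:rows, :cols]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec,
    tau_superior: float = 9.0,
    tau_inferior: float = 3.0,
    keep_masks: Optional[Sequence[str]] = None,
) -> tuple[CTVolume, PhantomTruth]:
    """Render one phantom volume and its ground truth.

    Parameters
    ----------
    spec : PhantomSpec
    tau_superior, tau_inferior : float
        Decision thresholds (mm) under which the truth flags are stated.
    keep_masks : sequence of str, optional
        Restrict the stored ground-truth masks to these organ names
        (default: keep all).
    """
    anat = spec.anatomy
    t = spec.slice_thickness
    rows, cols = spec.shape

    n_above = math.trunc(spec.superior_margin / t)  # rounded toward zero
    n_below = math.trunc(spec.inferior_margin / t)
    sup_mm = n_above * t
    inf_mm = n_below * t

    z_top = -sup_mm
    z_last = anat.kidney_span[1] - t + inf_mm
    n_slices = int(round((z_last - z_top) / t)) + 1
    if n_slices < 2:
        raise ValueError("margins leave fewer than 2 slices of coverage")
    z = z_top + t * np.arange(n_slices)  # anatomical z, inferior-positive

    # ---- in-plane templates (pixel units) -------------------------------
    rc, cc_ = rows // 2, cols // 2
    body = _ellipse(rows, cols, (rc, cc_), (0.32 * rows, 0.43 * cols))
    airway_center = (int(rc - 0.11 * rows), cc_)
    airway = _disk(rows, cols, airway_center, 4)
    ring = _disk(rows, cols, airway_center, 9) & ~_disk(rows, cols, airway_center, 6)
    cartilage2d = ring & (np.arange(rows)[:, None] <= airway_center[0] + 2)
    spine2d = _disk(rows, cols, (int(rc + 0.24 * rows), cc_), 7)
    lat = int(0.21 * cols)
    lungs2d = _ellipse(rows, cols, (rc - 2, cc_ - lat), (0.22 * rows, 0.17 * cols))
    lungs2d |= _ellipse(rows, cols, (rc - 2, cc_ + lat), (0.22 * rows, 0.17 * cols))
    pyr_off = int(0.085 * cols)
    pyriform2d = _disk(rows, cols, (airway_center[0] + 2, cc_ - pyr_off), 3)
    pyriform2d |= _disk(rows, cols, (airway_center[0] + 2, cc_ + pyr_off), 3)
    kid_row = int(rc + 0.19 * rows)
    kid_lat = int(0.20 * cols)
    fat2d = _ellipse(rows, cols, (kid_row, cc_ - kid_lat), (0.11 * rows, 0.125 * cols))
    fat2d |= _ellipse(rows, cols, (kid_row, cc_ + kid_lat), (0.11 * rows, 0.125 * cols))

    # ---- z-band membership ----------------------------------------------
    def band(span):
        return (z >= span[0]) & (z < span[1])

    in_lung = band(anat.lung_span)
    in_cart = band(anat.cartilage_span) if spec.cartilage_present else np.zeros_like(z, bool)
    in_pyr = band(anat.pyriform_span)
    in_airway = z < anat.airway_bottom
    if spec.closed_cord_span is not None:
        in_airway &= ~band(spec.closed_cord_span)
    fat_pad = 6.0
    in_fat = band((anat.kidney_span[0] - fat_pad, anat.kidney_span[1] + fat_pad))
    in_kidney = band(anat.kidney_span) if spec.kidneys_present else np.zeros_like(z, bool)

    label = np.zeros((n_slices, rows, cols), dtype=np.uint8)
    label[:, body] = _BODY
    for k in np.where(in_lung)[0]:
        label[k][lungs2d] = _LUNG
    for k in np.where(in_fat)[0]:
        label[k][fat2d] = _FAT
    kid_mid = 0.5 * (anat.kidney_span[0] + anat.kidney_span[1])
    kid_half = 0.5 * (anat.kidney_span[1] - anat.kidney_span[0])
    for k in np.where(in_kidney)[0]:
        frac = 1.0 - ((z[k] - kid_mid) / kid_half) ** 2
        scale = math.sqrt(max(frac, 0.05))  # floor keeps poles non-degenerate
        semi = (max(1.0, scale * 0.075 * rows), max(1.0, scale * 0.085 * cols))
        k2d = _ellipse(rows, cols, (kid_row, cc_ - kid_lat), semi)
        k2d |= _ellipse(rows, cols, (kid_row, cc_ + kid_lat), semi)
        label[k][k2d] = _KIDNEY
    label[:, spine2d] = _SPINE
    for k in np.where(in_cart)[0]:
        label[k][cartilage2d] = _CARTILAGE
    for k in np.where(in_airway)[0]:
        label[k][airway] = _AIRWAY
    for k in np.where(in_pyr)[0]:
        label[k][pyriform2d] = _PYRIFORM

    hu = _PALETTE[label]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, hu.shape).astype(np.float32)
    hu = np.clip(np.rint(hu), HU_CLIP[0], HU_CLIP[1]).astype(np.int16)

    # physical z decreases head -> feet; anatomical z increases
    z_phys = 500.0 - z
    volume = CTVolume(
        voxels=hu,
        slice_thickness=t,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        z_positions=z_phys,
        ctdi_vol=spec.ctdi_vol,
        series_id=spec.series_id or f"phantom-{spec.seed}",
    )

    all_masks = {
        "thyroid_cartilage": label == _CARTILAGE,
        "kidney": label == _KIDNEY,
        "lung": label == _LUNG,
        "airway": label == _AIRWAY,
        "pyriform_sinus": label == _PYRIFORM,
        "spine": label == _SPINE,
    }
    if keep_masks is not None:
        all_masks = {k: v for k, v in all_masks.items() if k in keep_masks}

    sup_over, inf_over, sup_under, inf_under = _truth_flags(
        sup_mm, inf_mm, anat, tau_superior, tau_inferior
    )
    truth = PhantomTruth(
        masks=all_masks,
        superior_excess_mm=sup_mm,
        inferior_excess_mm=inf_mm,
        superior_overscan=sup_over,
        inferior_overscan=inf_over,
        superior_underscan=sup_under,
        inferior_underscan=inf_under,
        tau_superior=tau_superior,
        tau_inferior=tau_inferior,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def draw_cohort_specs(
    n: int,
    prevalence: float = DEFAULT_PREVALENCE,
    seed: int = 0,
    tau_superior: float = 9.0,
    tau_inferior: float = 3.0,
    margin_gap: float = 2.0,
    underscan_fraction: float = 0.01,
    side_weights: tuple[float, float, float] = (0.6, 0.3, 0.1),
    noise_sigma: float = 20.0,
    slice_thickness: float = 1.0,
    shape: tuple[int, int] = (128, 128),
    anatomy: Optional[Anatomy] = None,
) -> list[PhantomSpec]:
    """Draw the per-case specs of a labelled cohort (reproducible by seed).

    The number of overscan cases is ``round(n * prevalence)``.  Overscan
    margins are drawn at least ``margin_gap`` mm beyond the threshold and
    acceptable margins at least ``margin_gap`` mm inside it, so the truth
    label is unambiguous at the stated thresholds.  A small fraction of
    the untagged cases are rendered as underscans (rare in practice);
    ``side_weights`` splits the tagged cases between superior-only,
    inferior-only and both-sided overscan.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if n == 0:
        return []
    anat = anatomy or Anatomy()
    rng = np.random.default_rng(seed)

    n_pos = int(round(n * prevalence))
    is_pos = np.zeros(n, dtype=bool)
    is_pos[:n_pos] = True
    rng.shuffle(is_pos)

    # margin windows (mm), all clear of the decision boundaries by margin_gap
    sup_ok = (0.0, max(0.0, tau_superior - margin_gap))
    sup_over = (tau_superior + margin_gap, tau_superior + margin_gap + 25.0)
    cart_len = anat.cartilage_span[1] - anat.cartilage_span[0]
    sup_under = (
        -(anat.airway_bottom - 15.0),
        -(cart_len + 8.0),
    )  # first slice inside lung, above the carina
    inf_ok = (-60.0, tau_inferior - margin_gap)
    inf_over = (tau_inferior + margin_gap, tau_inferior + margin_gap + 25.0)
    inf_under = (
        anat.lung_span[0] + 140.0 - anat.kidney_span[1],
        anat.lung_span[1] - 8.0 - anat.kidney_span[1],
    )  # last slice inside lung, above the kidney top

    specs: list[PhantomSpec] = []
    for i in range(n):
        if is_pos[i]:
            u = rng.random() * sum(side_weights)
            if u < side_weights[0]:
                side = "superior"
            elif u < side_weights[0] + side_weights[1]:
                side = "inferior"
            else:
                side = "both"
            s = rng.uniform(*sup_over) if side in ("superior", "both") else rng.uniform(*sup_ok)
            v = rng.uniform(*inf_over) if side in ("inferior", "both") else rng.uniform(*inf_ok)
        elif rng.random() < underscan_fraction:
            if rng.random() < 0.5:
                s, v = rng.uniform(*sup_under), rng.uniform(*inf_ok)
            else:
                s, v = rng.uniform(*sup_ok), rng.uniform(*inf_under)
        else:
            s, v = rng.uniform(*sup_ok), rng.uniform(*inf_ok)
        ctdi = float(np.exp(rng.normal(0.685, 0.630)))  # ~2.4 +- 1.7 mGy
        specs.append(
            PhantomSpec(
                shape=shape,
                slice_thickness=slice_thickness,
                superior_margin=float(s),
                inferior_margin=float(v),
                noise_sigma=noise_sigma,
                anatomy=anat,
                ctdi_vol=round(ctdi, 2),
                seed=int(rng.integers(2**31)),
                series_id=f"case-{i:04d}",
            )
        )
    return specs


def iter_cohort(
    n: int, prevalence: float = DEFAULT_PREVALENCE, seed: int = 0, **kwargs
) -> Iterator[tuple[CTVolume, PhantomTruth]]:
    """Generate a labelled cohort lazily (constant memory)."""
    tau_s = kwargs.get("tau_superior", 9.0)
    tau_i = kwargs.get("tau_inferior", 3.0)
    keep = kwargs.pop("keep_masks", None)
    for spec in draw_cohort_specs(n, prevalence, seed, **kwargs):
        yield generate_phantom(spec, tau_s, tau_i, keep_masks=keep)


def generate_cohort(
    n: int, prevalence: float = DEFAULT_PREVALENCE, seed: int = 0, **kwargs
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Materialize :func:`iter_cohort` as a list (small n only)."""
    return list(iter_cohort(n, prevalence, seed, **kwargs))


def truth_records(
    cases: Iterable[tuple[CTVolume, PhantomTruth]]
) -> list[GoldRecord]:
    """Gold-standard records (radiologist-tag stand-ins) for a cohort."""
    records = []
    for vol, truth in cases:
        if truth.superior_overscan and truth.inferior_overscan:
            side = "both"
        elif truth.superior_overscan:
            side = "superior"
        elif truth.inferior_overscan:
            side = "inferior"
        else:
            side = None
        records.append(
            GoldRecord(
                series_id=vol.series_id,
                overscan=truth.overscan,
                side=side,
                slice_thickness=vol.slice_thickness,
            )
        )
    return records


def export_cohort(
    cases: Iterable[tuple[CTVolume, PhantomTruth]], outdir
) -> Path:
    """Write a cohort as DICOM series plus a truth CSV readable by
    :func:`overscanqa.volume.read_gold_table`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    rows = []
    for vol, truth in cases:
        write_ct_series(vol, outdir / vol.series_id)
        rows.append(
            {
                "series_id": vol.series_id,
                "overscan": int(truth.overscan),
                "side": "superior"
                if truth.superior_overscan and not truth.inferior_overscan
                else "inferior"
                if truth.inferior_overscan and not truth.superior_overscan
                else ("both" if truth.overscan else ""),
                "superior_excess_mm": truth.superior_excess_mm,
                "inferior_excess_mm": truth.inferior_excess_mm,
                "underscan": int(truth.underscan),
            }
        )
    csv_path = outdir / "truth.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
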