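"""Four-compartment physiological partition of paired dual-tracer SPECT volumes.

The method fuses two co-registered hepatic SPECT scans: an intraarterial
Tc-99m MAA scan, whose count distribution simulates the subsequent Y-90
microsphere deposition, and an intravenous Tc-99m sulphur-colloid (SC) scan,
which labels functional (Kupffer-cell-bearing) liver parenchyma.  Each scan
is reduced to a binary map with a fractional threshold of its maximum
(default 10 %), and the two maps are fused into a voxelwise four-way
partition:

=========  ====  ===  =============================================
label      MAA   SC   interpretation
=========  ====  ===  =============================================
TUMOUR      +     -   viable tumour (microsphere-avid, non-functional)
FL_IR       +     +   irradiated functional liver (marginal/rim zone)
FL_UN       -     +   unirradiated functional liver
NULL        -     -   necrosis, vessels, cysts (inside the liver)
BACKGROUND  -     -   outside the hepatic envelope
=========  ====  ===  =============================================

The SC map is computed on a *corrected* SC volume (SC minus the residual
MAA signal, clipped at zero) because the MAA tracer is still in place when
the SC scan is acquired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

__all__ = [
    "Tracer",
    "Compartment",
    "SpectVolume",
    "BinaryMask",
    "CompartmentLabels",
    "VolumeReport",
    "fractional_threshold_mask",
    "corrected_tcsc",
    "partition_compartments",
    "compartment_volumes",
]


class Tracer:
    """Tracer identity tags for :class:`SpectVolume`."""

    TCMAA = "TcMAA"
    TCSC = "TcSC"
    TCSC_CORRECTED = "TcSC_corrected"


class Compartment(IntEnum):
    """Integer label codes used in label volumes (also on disk)."""

    BACKGROUND = 0
    TUMOUR = 1
    FL_IR = 2
    FL_UN = 3
    NULL = 4


#: Compartments that belong to the liver (everything except BACKGROUND).
HEPATIC_COMPARTMENTS = (
    Compartment.TUMOUR,
    Compartment.FL_IR,
    Compartment.FL_UN,
    Compartment.NULL,
)


@dataclass
class SpectVolume:
    """A reconstructed 3-D SPECT count volume with voxel spacing in mm.

    Parameters
    ----------
    counts
        Non-negative 3-D array of reconstructed counts.
    voxel_spacing
        ``(dx, dy, dz)`` voxel edge lengths in millimetres.
    tracer
        One of :class:`Tracer` (``"TcMAA"``, ``"TcSC"``, ``"TcSC_corrected"``).
    """

    counts: np.ndarray
    voxel_spacing: tuple[float, float, float]
    tracer: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be 3-D, got ndim={self.counts.ndim}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative everywhere")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def same_grid(self, other: "SpectVolume") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and self.voxel_spacing == other.voxel_spacing
        )


@dataclass
class BinaryMask:
    """Boolean voxel mask produced by fractional thresholding."""

    mask: np.ndarray
    source_tracer: str
    threshold_fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )


@dataclass
class CompartmentLabels:
    """Voxelwise compartment assignment (codes from :class:`Compartment`)."""

    labels: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = np.isin(self.labels, [int(c) for c in Compartment])
        if not valid.all():
            raise ValueError("labels contain codes outside the compartment set")
        self.labels = self.labels.astype(np.uint8)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    def mask(self, compartment: Compartment) -> np.ndarray:
        return self.labels == int(compartment)

    @property
    def hepatic_mask(self) -> np.ndarray:
        return self.labels != int(Compartment.BACKGROUND)


@dataclass
class VolumeReport:
    """Compartment volumes (mL) and fractions of total liver volume.

    ``v_fl_tot = v_fl_ir + v_fl_un`` and ``v_total_liver = v_t + v_fl_tot``;
    the null compartment is inside the liver envelope but, by definition,
    contains neither tumour nor functional tissue and is therefore not part
    of ``v_total_liver``.
    """

    v_t: float
    v_fl_ir: float
    v_fl_un: float
    v_null: float
    fractions: dict = field(init=False)

    def __post_init__(self) -> None:
        for name in ("v_t", "v_fl_ir", "v_fl_un", "v_null"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.v_total_liver
        self.fractions = {
            name: (vol / total if total > 0 else 0.0)
            for name, vol in (
                ("TUMOUR", self.v_t),
                ("FL_IR", self.v_fl_ir),
                ("FL_UN", self.v_fl_un),
                ("FL_TOT", self.v_fl_tot),
                ("NULL", self.v_null),
            )
        }

    @property
    def v_fl_tot(self) -> float:
        return self.v_fl_ir + self.v_fl_un

    @property
    def v_total_liver(self) -> float:
        return self.v_t + self.v_fl_tot

    def to_dict(self) -> dict:
        return {
            "units": "mL",
            "V_T": self.v_t,
            "V_FL_IR": self.v_fl_ir,
            "V_FL_UN": self.v_fl_un,
            "V_FL_TOT": self.v_fl_tot,
            "V_NULL": self.v_null,
            "V_TOTAL_LIVER": self.v_total_liver,
            "fractions_of_total_liver": dict(self.fractions),
        }


def fractional_threshold_mask(volume: SpectVolume, fraction: float = 0.10) -> BinaryMask:
    """Threshold a volume at ``fraction`` of its maximum voxel count.

    A voxel is positive when its count is greater than *or equal to*
    ``fraction * max(counts)`` (the boundary is inclusive).  The maximum is
    taken over the whole volume.

    Raises
    ------
    ValueError
        If the volume contains no positive voxel (the maximum is then not a
        usable reference) or ``fraction`` is outside ``(0, 1)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    peak = float(volume.counts.max())
    if peak <= 0:
        raise ValueError("cannot threshold an all-zero volume")
    mask = volume.counts >= fraction * peak
    return BinaryMask(mask=mask, source_tracer=volume.tracer, threshold_fraction=fraction)


def corrected_tcsc(sc: SpectVolume, maa: SpectVolume, maa_scale: float = 1.0) -> SpectVolume:
    """Subtract the residual MAA signal from the SC volume.

    Returns ``max(sc - maa_scale * maa, 0)`` voxelwise, tagged
    ``TcSC_corrected``.  ``maa_scale`` rescales the MAA image before
    subtraction (1.0 = plain subtraction); negative results are clipped to
    zero since counts cannot be negative.
    """
    if maa_scale < 0:
        raise ValueError(f"maa_scale must be non-negative, got {maa_scale}")
    if not sc.same_grid(maa):
        raise ValueError(
            "SC and MAA volumes must share grid shape and spacing: "
            f"{sc.counts.shape}/{sc.voxel_spacing} vs {maa.counts.shape}/{maa.voxel_spacing}"
        )
    corrected = np.clip(sc.counts - maa_scale * maa.counts, 0.0, None)
    return SpectVolume(counts=corrected, voxel_spacing=sc.voxel_spacing, tracer=Tracer.TCSC_CORRECTED)


def _default_envelope(union: np.ndarray) -> np.ndarray:
    """Hepatic envelope inferred from the mask union.

    Morphological closing bridges thin gaps between the two maps, then hole
    filling absorbs fully enclosed cold cavities (necrotic cores, cysts) so
    that they are labelled NULL rather than BACKGROUND.
    """
    closed = ndimage.binary_closing(union, structure=ndimage.generate_binary_structure(3, 1))
    # closing can clip true-positive voxels touching the array border; keep union
    closed |= union
    return ndimage.binary_fill_holes(closed)


def partition_compartments(
    maa_mask: BinaryMask,
    sc_mask: BinaryMask,
    liver_envelope: np.ndarray | None = None,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CompartmentLabels:
    """Fuse the MAA and SC binary maps into the four-compartment partition.

    Voxels positive on both tracers are irradiated functional liver (FL_IR),
    MAA-only voxels tumour, SC-only voxels unirradiated functional liver
    (FL_UN).  Double-negative voxels are NULL inside the hepatic envelope and
    BACKGROUND outside.  When no envelope is supplied it is inferred from
    the morphological closure (closing + hole fill) of the mask union.
    """
    m = maa_mask.mask
    s = sc_mask.mask
    if m.shape != s.shape:
        raise ValueError(f"mask shape mismatch: {m.shape} vs {s.shape}")
    if liver_envelope is None:
        envelope = _default_envelope(m | s)
    else:
        envelope = np.asarray(liver_envelope, dtype=bool)
        if envelope.shape != m.shape:
            raise ValueError(f"liver_envelope shape {envelope.shape} != mask shape {m.shape}")

    labels = np.full(m.shape, int(Compartment.BACKGROUND), dtype=np.uint8)
    labels[m & ~s] = int(Compartment.TUMOUR)
    labels[m & s] = int(Compartment.FL_IR)
    labels[~m & s] = int(Compartment.FL_UN)
    labels[~m & ~s & envelope] = int(Compartment.NULL)
    return CompartmentLabels(labels=labels, voxel_spacing=voxel_spacing)


def compartment_volumes(
    labels: CompartmentLabels,
    voxel_spacing: tuple[float, float, float] | None = None,
) -> VolumeReport:
    """Convert voxel counts per compartment into volumes in mL."""
    spacing = labels.voxel_spacing if voxel_spacing is None else tuple(map(float, voxel_spacing))
    voxel_ml = float(np.prod(spacing)) / 1000.0
    count = lambda c: int(np.count_nonzero(labels.labels == int(c)))
    return VolumeReport(
        v_t=count(Compartment.TUMOUR) * voxel_ml,
        v_fl_ir=count(Compartment.FL_IR) * voxel_ml,
        v_fl_un=count(Compartment.FL_UN) * voxel_ml,
        v_null=count(Compartment.NULL) * voxel_ml,
    )
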