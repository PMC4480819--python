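"""Digital dual-tracer hepatic SPECT phantom with analytic ground truth.

The phantom emulates the paired-scan acquisition the partition method
consumes: an ellipsoidal liver filled with sulphur-colloid-avid functional
parenchyma, containing spherical MAA-avid tumours, each optionally wrapped
in a hypervascular rim (avid on *both* tracers) and cored by cold necrosis
(avid on neither).  Geometry is analytic, so every compartment volume and
dose is known in closed form up to voxelization.

Acquisition model
-----------------
The MAA scan records the intraarterial tracer alone.  The second (SC) scan
is acquired minutes later *with the MAA tracer still lodged in the liver*,
so the observed SC volume is the colloid distribution plus the residual MAA
signal — exactly the situation the downstream MAA-subtraction step is
designed to undo.  Degradation is an isotropic Gaussian blur (system
resolution surrogate) applied to the clean activity patterns, followed by
voxelwise Poisson sampling.  Ground-truth labels are defined on the
pre-blur, pre-noise geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dosimetry import DoseReport, compartment_absorbed_dose
from .segmentation import (
    Compartment,
    CompartmentLabels,
    SpectVolume,
    Tracer,
    VolumeReport,
    compartment_volumes,
)

__all__ = [
    "TumourSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "analytic_dose",
    "random_phantom_spec",
]


@dataclass
class TumourSpec:
    """One spherical tumour: centre/radius in mm (physical coordinates),
    MAA avidity of the viable shell, an optional hypervascular rim outside
    the tumour boundary, and an optional cold necrotic core."""

    centre: tuple[float, float, float]
    radius: float
    maa_intensity: float = 1.0
    rim_width: float = 0.0
    rim_maa_intensity: float = 0.0
    necrotic_core_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tumour radius must be positive")
        if self.necrotic_core_radius >= self.radius:
            raise ValueError("necrotic core must be strictly inside the tumour")
        if min(self.maa_intensity, self.rim_maa_intensity, self.rim_width,
               self.necrotic_core_radius) < 0:
            raise ValueError("tumour intensities, rim width and core radius must be >= 0")


@dataclass
class PhantomSpec:
    """Generative parameters for one dual-tracer phantom.

    Intensities are relative activity concentrations (arbitrary units);
    absolute count scales are set by ``total_maa_counts`` /
    ``total_sc_counts``.  ``psf_sigma`` is the Gaussian blur in mm (0
    disables), ``noise`` is ``"none"`` or ``"poisson"``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (4.42, 4.42, 4.42)
    liver_centre: tuple[float, float, float] = (141.0, 141.0, 141.0)
    liver_axes: tuple[float, float, float] = (90.0, 65.0, 75.0)
    tumours: tuple[TumourSpec, ...] = ()
    parenchyma_sc_intensity: float = 1.0
    background_intensity: float = 0.0
    total_maa_counts: float = 5e5
    total_sc_counts: float = 5e6
    psf_sigma: float = 0.0
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if any(a <= 0 for a in self.liver_axes):
            raise ValueError("liver semi-axes must be positive")
        if self.parenchyma_sc_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.total_maa_counts <= 0 or self.total_sc_counts <= 0:
            raise ValueError("total counts must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        self.tumours = tuple(
            t if isinstance(t, TumourSpec) else TumourSpec(**t) for t in self.tumours
        )
        for t in self.tumours:
            self._check_inside_liver(t)

    def _check_inside_liver(self, t: TumourSpec) -> None:
        # sufficient condition: scaled centre offset plus outer radius over
        # the smallest semi-axis stays within the unit ball
        offset = np.asarray(t.centre, float) - np.asarray(self.liver_centre, float)
        scaled = np.linalg.norm(offset / np.asarray(self.liver_axes, float))
        outer = t.radius + t.rim_width
        if scaled + outer / min(self.liver_axes) > 1.0:
            raise ValueError(
                f"tumour at {t.centre} (outer radius {outer} mm) extends outside the liver"
            )


@dataclass
class GroundTruth:
    """Pre-degradation truth for a generated phantom."""

    label_volume: CompartmentLabels
    true_volumes: VolumeReport
    true_dose_report: DoseReport | None


def _voxel_centres(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * d
        for n, d in zip(spec.grid_shape, spec.voxel_spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _geometry_masks(spec: PhantomSpec) -> dict:
    """Boolean membership masks from the analytic geometry."""
    xx, yy, zz = _voxel_centres(spec)
    cx, cy, cz = spec.liver_centre
    ax, ay, az = spec.liver_axes
    liver = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0

    shape = tuple(spec.grid_shape)
    tumour = np.zeros(shape, dtype=bool)   # viable shell (MAA-avid, SC-cold)
    rim = np.zeros(shape, dtype=bool)      # hypervascular rim (both tracers)
    core = np.zeros(shape, dtype=bool)     # cold necrosis
    tumour_intensity = np.zeros(shape)
    rim_intensity = np.zeros(shape)
    for t in spec.tumours:
        d2 = (xx - t.centre[0]) ** 2 + (yy - t.centre[1]) ** 2 + (zz - t.centre[2]) ** 2
        inside = d2 <= t.radius**2
        this_core = d2 <= t.necrotic_core_radius**2 if t.necrotic_core_radius > 0 else np.zeros(shape, bool)
        this_shell = inside & ~this_core
        this_rim = (
            (d2 <= (t.radius + t.rim_width) ** 2) & ~inside
            if t.rim_width > 0 and t.rim_maa_intensity > 0
            else np.zeros(shape, bool)
        )
        tumour |= this_shell
        core |= this_core
        rim |= this_rim
        tumour_intensity[this_shell] = np.maximum(tumour_intensity[this_shell], t.maa_intensity)
        rim_intensity[this_rim] = np.maximum(rim_intensity[this_rim], t.rim_maa_intensity)
    # overlap precedence: viable tumour > core > rim
    core &= ~tumour
    rim &= ~(tumour | core)
    rim &= liver
    parenchyma = liver & ~(tumour | core)  # rim is functional tissue too
    return {
        "liver": liver,
        "tumour": tumour,
        "rim": rim,
        "core": core,
        "parenchyma": parenchyma,
        "tumour_intensity": tumour_intensity,
        "rim_intensity": rim_intensity,
    }


def _activity_patterns(spec: PhantomSpec, geo: dict) -> tuple[np.ndarray, np.ndarray]:
    """Clean (relative) activity concentration patterns for MAA and SC."""
    background = ~geo["liver"]
    maa = geo["tumour_intensity"] * geo["tumour"] + geo["rim_intensity"] * geo["rim"]
    sc = spec.parenchyma_sc_intensity * geo["parenchyma"].astype(float)
    if spec.background_intensity > 0:
        maa = maa + spec.background_intensity * background
        sc = sc + spec.background_intensity * background
    return maa, sc


def _scaled_counts(pattern: np.ndarray, total: float) -> np.ndarray:
    s = pattern.sum()
    if s <= 0:
        return np.zeros_like(pattern)
    return pattern * (total / s)


def ground_truth_labels(spec: PhantomSpec) -> CompartmentLabels:
    """Voxelized compartment labels from the analytic geometry."""
    geo = _geometry_masks(spec)
    labels = np.full(tuple(spec.grid_shape), int(Compartment.BACKGROUND), dtype=np.uint8)
    labels[geo["parenchyma"]] = int(Compartment.FL_UN)
    labels[geo["rim"]] = int(Compartment.FL_IR)
    labels[geo["tumour"]] = int(Compartment.TUMOUR)
    labels[geo["core"]] = int(Compartment.NULL)
    return CompartmentLabels(labels=labels, voxel_spacing=spec.voxel_spacing)


def generate_phantom(
    spec: PhantomSpec,
    administered_gbq: float | None = None,
) -> tuple[SpectVolume, SpectVolume, GroundTruth]:
    """Generate a co-registered (MAA, observed SC) volume pair with truth.

    The observed SC scan includes the residual MAA signal (the MAA tracer
    is still in place during the second acquisition), which is what the
    segmentation module's subtraction step removes.  With ``noise="none"``
    and ``psf_sigma=0`` the default-threshold segmentation recovers the
    ground-truth labels exactly.  Runs are reproducible per seed.

    When ``administered_gbq`` is given, the ground truth also carries the
    analytic dose report for that administration.
    """
    geo = _geometry_masks(spec)
    maa_pattern, sc_pattern = _activity_patterns(spec, geo)
    maa_clean = _scaled_counts(maa_pattern, spec.total_maa_counts)
    sc_clean = _scaled_counts(sc_pattern, spec.total_sc_counts)

    maa_counts = maa_clean.copy()
    sc_counts = sc_clean + maa_clean  # MAA residual present in the SC scan
    if spec.psf_sigma > 0:
        sigma_vox = [spec.psf_sigma / d for d in spec.voxel_spacing]
        maa_counts = ndimage.gaussian_filter(maa_counts, sigma_vox)
        sc_counts = ndimage.gaussian_filter(sc_counts, sigma_vox)
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        maa_counts = rng.poisson(maa_counts).astype(float)
        sc_counts = rng.poisson(sc_counts).astype(float)

    maa = SpectVolume(maa_counts, spec.voxel_spacing, Tracer.TCMAA)
    sc = SpectVolume(sc_counts, spec.voxel_spacing, Tracer.TCSC)

    labels = ground_truth_labels(spec)
    truth = GroundTruth(
        label_volume=labels,
        true_volumes=compartment_volumes(labels),
        true_dose_report=None if administered_gbq is None else analytic_dose(spec, administered_gbq),
    )
    return maa, sc, truth


def random_phantom_spec(
    seed: int,
    noise: str = "none",
    psf_sigma: float = 0.0,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    voxel_spacing: tuple[float, float, float] = (4.42, 4.42, 4.42),
) -> PhantomSpec:
    """Seeded random phantom: 1-3 tumours with varying size, position,
    rim and necrotic core, inside a fixed liver ellipsoid.

    Tracer avidities stay at the defaults (tumour MAA 1.0, rim 0.3, both
    above the 10 % threshold), so on noise-free unblurred output the
    default segmentation recovers the ground-truth labels exactly.
    """
    rng = np.random.default_rng(seed)
    extent = [n * d for n, d in zip(grid_shape, voxel_spacing)]
    centre = tuple(e / 2.0 for e in extent)
    axes = (
        min(90.0, 0.42 * extent[0]),
        min(65.0, 0.42 * extent[1]),
        min(75.0, 0.42 * extent[2]),
    )
    tumours = []
    for _ in range(int(rng.integers(1, 4))):
        radius = float(rng.uniform(15.0, 28.0))
        rim_width = float(rng.uniform(4.0, 8.0))
        core = float(rng.uniform(0.0, 0.45)) * radius
        # place the tumour so sphere + rim provably fit inside the ellipsoid
        outer = radius + rim_width
        margin = 1.0 - outer / min(axes)
        if margin <= 0:
            continue
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        r_scaled = float(rng.uniform(0.0, 0.95 * margin))
        offset = direction * r_scaled * np.asarray(axes)
        tumours.append(
            TumourSpec(
                centre=tuple(np.asarray(centre) + offset),
                radius=radius,
                rim_width=rim_width,
                rim_maa_intensity=0.3,
                necrotic_core_radius=core if core > 3.0 else 0.0,
            )
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_spacing=voxel_spacing,
        liver_centre=centre,
        liver_axes=axes,
        tumours=tuple(tumours),
        psf_sigma=psf_sigma,
        noise=noise,
        seed=seed,
    )


def analytic_dose(spec: PhantomSpec, administered_gbq: float) -> DoseReport:
    """Closed-form dose report from the generative (noise-free) phantom.

    Activity fractions come directly from the clean MAA concentration
    pattern integrated over each geometric compartment, volumes from the
    voxelized geometry — independent of the threshold/partition pipeline,
    so this serves as its oracle.
    """
    if administered_gbq < 0:
        raise ValueError("administered_gbq must be non-negative")
    geo = _geometry_masks(spec)
    maa_pattern, _ = _activity_patterns(spec, geo)
    maa_clean = _scaled_counts(maa_pattern, spec.total_maa_counts)

    labels = ground_truth_labels(spec)
    volumes = compartment_volumes(labels)
    hepatic = labels.hepatic_mask
    total = float(maa_clean[hepatic].sum())
    counts = {
        comp.name: float(maa_clean[labels.mask(comp)].sum())
        for comp in (Compartment.TUMOUR, Compartment.FL_IR, Compartment.FL_UN, Compartment.NULL)
    }
    if total <= 0:
        # no hepatic MAA signal at all: every dose is zero
        fractions = {k: 0.0 for k in counts}
        return DoseReport(administered_gbq, 0.0, 0.0, 0.0, 0.0, volumes, fractions)
    fractions = {k: c / total for k, c in counts.items()}

    def dose(count: float, vol_ml: float) -> float:
        if vol_ml <= 0:
            return 0.0
        return compartment_absorbed_dose(count, total, administered_gbq, vol_ml / 1000.0)

    return DoseReport(
        administered_gbq=float(administered_gbq),
        d_t=dose(counts["TUMOUR"], volumes.v_t),
        d_fl_ir=dose(counts["FL_IR"], volumes.v_fl_ir),
        d_fl_tot=dose(counts["FL_IR"], volumes.v_fl_tot),
        d_fl_un=0.0,
        volumes=volumes,
        activity_fractions=fractions,
    )
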