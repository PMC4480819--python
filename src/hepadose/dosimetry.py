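"""MIRD compartment dosimetry, activity prescription and planning rules.

The mean absorbed dose to a compartment follows the single-compartment MIRD
conversion for Y-90::

    D [Gy] = (compartment counts / total hepatic counts)
             * A [GBq] * (1 / 1.029 kg/L) * (1 / V [L]) * 50

where 1.029 kg/L is the specific density of hepatic tissue and 50 converts
GBq/kg of Y-90 into Gy.  The fraction of administered activity reaching a
compartment is estimated from the MAA count distribution; the denominator
is the *total* hepatic MAA signal (all four compartments), so thresholding
only affects which counts are attributed to which numerator.

By convention the unirradiated functional liver (sub-threshold MAA) is
assigned zero dose, and the total-functional-liver dose spreads the
irradiated-compartment energy over the full functional volume:
``D_FL_TOT * V_FL_TOT = D_FL_IR * V_FL_IR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import (
    Compartment,
    CompartmentLabels,
    SpectVolume,
    VolumeReport,
    compartment_volumes,
)

__all__ = [
    "HEPATIC_DENSITY_KG_PER_L",
    "Y90_GY_PER_GBQ_PER_KG",
    "TUMOUR_DOSE_FLOOR_GY",
    "FL_DOSE_SAFE_GY",
    "FL_DOSE_HIGH_RISK_GY",
    "DoseReport",
    "PlanningInput",
    "PlanningRecommendation",
    "compartment_absorbed_dose",
    "dose_report",
    "cumulative_fl_dose",
    "prescribe_activity_bsa",
    "prescribe_activity_glass",
    "planning_recommendation",
]

#: Specific density of hepatic tissue (kg per litre).
HEPATIC_DENSITY_KG_PER_L = 1.029
#: Y-90 conversion factor from GBq/kg to Gy.
Y90_GY_PER_GBQ_PER_KG = 50.0

#: Tumour-dose efficacy floor (Gy): above it a ~50 % objective response
#: rate was observed irrespective of cell type.
TUMOUR_DOSE_FLOOR_GY = 32.7
#: Cumulative functional-liver dose below which no REILD was observed.
FL_DOSE_SAFE_GY = 30.0
#: Cumulative functional-liver dose above which REILD risk rises steeply.
FL_DOSE_HIGH_RISK_GY = 60.0


@dataclass
class DoseReport:
    """Absorbed doses (Gy) and activity fractions for one administration."""

    administered_gbq: float
    d_t: float
    d_fl_ir: float
    d_fl_tot: float
    d_fl_un: float
    volumes: VolumeReport
    activity_fractions: dict

    @property
    def ratio_t_fl(self) -> float | None:
        """Physiological tumour-to-functional-liver dose ratio.

        ``None`` (missing, not infinity) when the functional-liver dose is
        zero.
        """
        if self.d_fl_tot == 0:
            return None
        return self.d_t / self.d_fl_tot

    def to_dict(self) -> dict:
        return {
            "administered_activity_gbq": self.administered_gbq,
            "doses_gy": {
                "D_T": round(self.d_t, 1),
                "D_FL_IR": round(self.d_fl_ir, 1),
                "D_FL_TOT": round(self.d_fl_tot, 1),
                "D_FL_UN": round(self.d_fl_un, 1),
            },
            "ratio_T_FL": None if self.ratio_t_fl is None else round(self.ratio_t_fl, 3),
            "activity_fractions": {k: round(v, 6) for k, v in self.activity_fractions.items()},
            "volumes": self.volumes.to_dict(),
        }


@dataclass
class PlanningInput:
    """Inputs for activity prescription and safety evaluation."""

    bsa: float
    liver_involvement: float
    target_dose: float = 105.0
    target_mass: float = 1.8
    prior_liver_dose: float = 0.0

    def __post_init__(self) -> None:
        if self.bsa <= 0:
            raise ValueError("bsa must be positive")
        if not 0.0 <= self.liver_involvement <= 1.0:
            raise ValueError("liver_involvement must be a fraction in [0, 1]")
        if self.target_dose <= 0:
            raise ValueError("target_dose must be positive")
        if self.prior_liver_dose < 0:
            raise ValueError("prior_liver_dose must be non-negative")


def compartment_absorbed_dose(
    compartment_counts: float,
    total_counts: float,
    administered_gbq: float,
    volume_l: float,
) -> float:
    """Mean absorbed dose (Gy) to one compartment via the MIRD conversion."""
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if volume_l <= 0:
        raise ValueError("volume_l must be positive")
    if administered_gbq < 0:
        raise ValueError("administered_gbq must be non-negative")
    if not 0 <= compartment_counts <= total_counts:
        raise ValueError("compartment_counts must lie in [0, total_counts]")
    fraction = compartment_counts / total_counts
    return (
        fraction
        * administered_gbq
        * (1.0 / HEPATIC_DENSITY_KG_PER_L)
        * (1.0 / volume_l)
        * Y90_GY_PER_GBQ_PER_KG
    )


def dose_report(
    labels: CompartmentLabels,
    maa: SpectVolume,
    administered_gbq: float,
) -> DoseReport:
    """Compartment absorbed doses from a partition and the original MAA scan.

    Counts are summed from the raw (unthresholded) MAA volume over each
    label region; the normalisation denominator is the total hepatic MAA
    signal (tumour + FL_IR + FL_UN + NULL), so sub-threshold activity
    dilutes every compartment dose rather than being redistributed.
    """
    if labels.labels.shape != maa.counts.shape:
        raise ValueError(
            f"labels shape {labels.labels.shape} != MAA shape {maa.counts.shape}"
        )
    if administered_gbq < 0:
        raise ValueError("administered_gbq must be non-negative")
    hepatic = labels.hepatic_mask
    if not hepatic.any():
        raise ValueError("no hepatic voxels in label volume")
    total = float(maa.counts[hepatic].sum())
    if total <= 0:
        raise ValueError("no MAA counts inside the hepatic region")

    counts = {
        comp.name: float(maa.counts[labels.mask(comp)].sum())
        for comp in (Compartment.TUMOUR, Compartment.FL_IR, Compartment.FL_UN, Compartment.NULL)
    }
    fractions = {name: c / total for name, c in counts.items()}
    volumes = compartment_volumes(labels)

    def dose(count: float, vol_ml: float) -> float:
        if vol_ml <= 0:
            return 0.0
        return compartment_absorbed_dose(count, total, administered_gbq, vol_ml / 1000.0)

    d_t = dose(counts["TUMOUR"], volumes.v_t)
    d_fl_ir = dose(counts["FL_IR"], volumes.v_fl_ir)
    # FL_IR energy spread over the whole functional liver; FL_UN itself
    # carries zero dose by convention.
    d_fl_tot = dose(counts["FL_IR"], volumes.v_fl_tot)
    return DoseReport(
        administered_gbq=float(administered_gbq),
        d_t=d_t,
        d_fl_ir=d_fl_ir,
        d_fl_tot=d_fl_tot,
        d_fl_un=0.0,
        volumes=volumes,
        activity_fractions=fractions,
    )


def cumulative_fl_dose(d_fl_tot: float, prior_liver_dose: float) -> float:
    """Cumulative functional-liver dose: this administration plus the mean
    liver dose from prior radiation (DVH-derived scalar), in Gy."""
    if d_fl_tot < 0 or prior_liver_dose < 0:
        raise ValueError("doses must be non-negative")
    return d_fl_tot + prior_liver_dose


def prescribe_activity_bsa(bsa: float, liver_involvement: float) -> float:
    """Resin-microsphere activity (GBq) from body surface area and tumour
    liver involvement: ``BSA (m^2) - 0.2 + LI``, floored at zero."""
    if bsa <= 0:
        raise ValueError("bsa must be positive")
    if not 0.0 <= liver_involvement <= 1.0:
        raise ValueError("liver_involvement must be in [0, 1]")
    return max(bsa - 0.2 + liver_involvement, 0.0)


def prescribe_activity_glass(target_dose: float, target_mass: float) -> float:
    """Glass-microsphere activity (GBq) delivering ``target_dose`` Gy to a
    target territory of ``target_mass`` kg (MIRD inversion, 50 Gy·kg/GBq)."""
    if target_dose <= 0 or target_mass <= 0:
        raise ValueError("target_dose and target_mass must be positive")
    return target_dose * target_mass / Y90_GY_PER_GBQ_PER_KG


@dataclass
class PlanningRecommendation:
    """Threshold-based planning verdict for one dose report."""

    action: str  # one of {"increase_activity", "acceptable", "reduce_activity"}
    efficacy_met: bool
    fl_band: str  # one of {"safe", "caution", "high_reild_risk"}
    cumulative_fl_dose_gy: float
    d_t_gy: float

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "efficacy_met": self.efficacy_met,
            "fl_band": self.fl_band,
            "cumulative_FL_dose_gy": round(self.cumulative_fl_dose_gy, 1),
            "D_T_gy": round(self.d_t_gy, 1),
            "thresholds_gy": {
                "tumour_dose_floor": TUMOUR_DOSE_FLOOR_GY,
                "fl_safe_below": FL_DOSE_SAFE_GY,
                "fl_high_risk_above": FL_DOSE_HIGH_RISK_GY,
            },
        }


def classify_fl_band(cumulative_gy: float) -> str:
    """REILD risk band for a cumulative functional-liver dose.

    ``< 30`` Gy is safe (no REILD observed), ``30 - 60`` Gy inclusive is the
    tolerated caution band, ``> 60`` Gy carries a ~38 % REILD risk.
    """
    if cumulative_gy < FL_DOSE_SAFE_GY:
        return "safe"
    if cumulative_gy > FL_DOSE_HIGH_RISK_GY:
        return "high_reild_risk"
    return "caution"


def planning_recommendation(report: DoseReport, prior_liver_dose: float = 0.0) -> PlanningRecommendation:
    """Dose-threshold treatment-planning verdict.

    Aim for a tumour dose above the 32.7 Gy efficacy floor (strict ``>``)
    while keeping the cumulative functional-liver dose out of the >60 Gy
    high-REILD-risk band; activity may be increased only when the
    cumulative dose is in the safe (<30 Gy) band.
    """
    cumulative = cumulative_fl_dose(report.d_fl_tot, prior_liver_dose)
    band = classify_fl_band(cumulative)
    efficacy_met = report.d_t > TUMOUR_DOSE_FLOOR_GY
    if band == "high_reild_risk":
        action = "reduce_activity"
    elif not efficacy_met and band == "safe":
        action = "increase_activity"
    else:
        action = "acceptable"
    return PlanningRecommendation(
        action=action,
        efficacy_met=efficacy_met,
        fl_band=band,
        cumulative_fl_dose_gy=cumulative,
        d_t_gy=report.d_t,
    )
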