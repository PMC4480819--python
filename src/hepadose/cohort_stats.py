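"""Dose–response statistics over patient cohorts.

Aggregates per-patient records (compartment doses, RECIST/mRECIST response
labels, NCI-CTCAE toxicity grades, REILD flags, survival) into the summary
statistics used to validate the dual-tracer dosimetry method: pooled
objective response rates, Kaplan-Meier survival with (stratified) log-rank
comparisons, r x c chi-squared tests, rank tests, toxicity grade change and
REILD incidence by cumulative functional-liver dose band.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .dosimetry import FL_DOSE_HIGH_RISK_GY, FL_DOSE_SAFE_GY

__all__ = [
    "CELL_TYPES",
    "RESPONSE_LABELS",
    "RESPONDER_LABELS",
    "PatientRecord",
    "ResponseTable",
    "pooled_response_rate",
    "km_curve",
    "logrank",
    "chi_squared_rxc",
    "rank_compare",
    "toxicity_grade_change",
    "reild_band_summary",
    "load_outcome_counts",
    "response_table_from_counts",
    "records_to_frame",
    "frame_to_records",
]

CELL_TYPES = ("HCC", "CCA", "NET", "CRC", "other")
RESPONSE_LABELS = ("CR", "PR", "SD", "PD", "not_evaluable")
#: Objective response = complete or partial response.
RESPONDER_LABELS = frozenset({"CR", "PR"})


@dataclass
class PatientRecord:
    """One patient's dosimetry, outcome and follow-up summary.

    Toxicity grades are NCI-CTCAE integers 0-4 per laboratory value
    (e.g. bilirubin, AST, ALT); ``survival_months`` is from treatment and
    ``event`` is True for observed death (False = censored).
    """

    cell_type: str
    d_t: float
    d_fl_tot: float
    prior_liver_dose: float = 0.0
    response_3m: str = "not_evaluable"
    response_6m: str = "not_evaluable"
    baseline_grades: dict = field(default_factory=dict)
    max_followup_grades: dict = field(default_factory=dict)
    reild: bool = False
    survival_months: float = 0.0
    event: bool = False

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.response_3m not in RESPONSE_LABELS or self.response_6m not in RESPONSE_LABELS:
            raise ValueError("response labels must be CR/PR/SD/PD/not_evaluable")
        if min(self.d_t, self.d_fl_tot, self.prior_liver_dose) < 0:
            raise ValueError("doses must be non-negative")
        if self.survival_months < 0:
            raise ValueError("survival_months must be non-negative")
        for grades in (self.baseline_grades, self.max_followup_grades):
            for lab, g in grades.items():
                if not 0 <= int(g) <= 4:
                    raise ValueError(f"grade for {lab} outside 0-4: {g}")

    @property
    def cumulative_fl_dose(self) -> float:
        return self.d_fl_tot + self.prior_liver_dose


@dataclass
class ResponseTable:
    """Per-group (responders, evaluable) counts at one timepoint."""

    groups: dict  # name -> (responders, evaluable)

    def __post_init__(self) -> None:
        for name, (r, n) in self.groups.items():
            if n < 0 or r < 0 or r > n:
                raise ValueError(f"invalid counts for group {name!r}: {r}/{n}")


def pooled_response_rate(table: ResponseTable) -> dict:
    """Pooled objective response rate over all groups.

    Returns the percentage (responders / evaluable x 100) plus the pooled
    numerator and denominator.  Invariant to group ordering and merging.
    """
    responders = sum(r for r, _ in table.groups.values())
    evaluable = sum(n for _, n in table.groups.values())
    if evaluable == 0:
        raise ValueError("no evaluable patients")
    return {
        "responders": int(responders),
        "evaluable": int(evaluable),
        "rate_percent": 100.0 * responders / evaluable,
    }


def km_curve(times, events) -> dict:
    """Kaplan-Meier product-limit survival estimate.

    Returns the step function (event/censoring times and survival
    probabilities), the median survival time (smallest t with S(t) <= 0.5;
    ``None`` when never reached) and its 95 % confidence band.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    median = kmf.median_survival_time_
    ci = kmf.confidence_interval_survival_function_
    return {
        "times": sf.index.to_numpy(dtype=float),
        "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        "ci_lower": ci.iloc[:, 0].to_numpy(dtype=float),
        "ci_upper": ci.iloc[:, 1].to_numpy(dtype=float),
        "median": None if np.isinf(median) else float(median),
    }


def _logrank_oe_cov(durations, observed, labels, k):
    """Observed-minus-expected vector and its covariance for one stratum.

    Standard hypergeometric moments at each distinct event time, with the
    tie-corrected variance factor ``d (n - d) / (n - 1)``.
    """
    z = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(durations[observed]):
        at_risk = durations >= t
        n = int(at_risk.sum())
        events_here = observed & (durations == t)
        d = int(events_here.sum())
        if n == 0 or d == 0:
            continue
        n_i = np.array([(at_risk & (labels == i)).sum() for i in range(k)], dtype=float)
        d_i = np.array([(events_here & (labels == i)).sum() for i in range(k)], dtype=float)
        p_i = n_i / n
        z += d_i - d * p_i
        if n > 1:
            factor = d * (n - d) / (n - 1)
            cov += factor * (np.diag(p_i) - np.outer(p_i, p_i))
    return z, cov


def logrank(groups, strata=None) -> dict:
    """Log-rank test across two or more survival groups.

    ``groups`` is a list of ``(times, events)`` pairs.  With ``strata`` (a
    list of per-subject stratum labels, one array per group), the
    observed-minus-expected vectors and covariance matrices are summed
    across strata (Mantel-Haenszel pooling) before forming the chi-squared
    statistic with k - 1 degrees of freedom.  The unstratified case is
    delegated to lifelines.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    durations, observed, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {i} has no subjects")
        durations.append(t)
        observed.append(e)
        labels.append(np.full(t.size, i))
    durations = np.concatenate(durations)
    observed = np.concatenate(observed)
    labels = np.concatenate(labels)
    k = len(groups)
    df = k - 1

    if strata is None:
        res = multivariate_logrank_test(durations, labels, observed)
        return {"statistic": float(res.test_statistic), "df": df, "p": float(res.p_value)}

    strata_arr = np.concatenate([np.asarray(s) for s in strata])
    if strata_arr.size != durations.size:
        raise ValueError("strata must match the subject layout of groups")
    z = np.zeros(k)
    cov = np.zeros((k, k))
    for stratum in np.unique(strata_arr):
        sel = strata_arr == stratum
        z_s, cov_s = _logrank_oe_cov(durations[sel], observed[sel], labels[sel], k)
        z += z_s
        cov += cov_s
    # the k-vector sums to zero; drop the last component for a full-rank form
    statistic = float(z[:df] @ np.linalg.solve(cov[:df, :df], z[:df]))
    return {"statistic": statistic, "df": df, "p": float(stats.chi2.sf(statistic, df))}


def chi_squared_rxc(table) -> dict:
    """Pearson chi-squared test on an r x c contingency table.

    No continuity correction; df = (r-1)(c-1), upper-tail p-value.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("every row and column must have a positive total")
    statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(statistic), "df": int(df), "p": float(p)}


#: Largest combined sample size for which the Mann-Whitney p-value is
#: computed by exact enumeration (ties force the normal approximation).
_MWU_EXACT_MAX_N = 10


def rank_compare(groups) -> dict:
    """Nonparametric comparison of two or more numeric samples.

    Two groups: two-sided Mann-Whitney U — exact enumeration when the
    combined sample size is at most 10 and tie-free, otherwise the normal
    approximation with tie correction (no continuity correction).  More
    than two groups: Kruskal-Wallis H with tie correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if len(arrays) == 2:
        a, b = arrays
        pooled = np.concatenate([a, b])
        exact = (a.size + b.size <= _MWU_EXACT_MAX_N) and (np.unique(pooled).size == pooled.size)
        if exact:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            )
        return {"test": "mann-whitney", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.kruskal(*arrays)
    return {"test": "kruskal-wallis", "statistic": float(res.statistic), "p": float(res.pvalue)}


def toxicity_grade_change(baseline: dict, followup: dict) -> int:
    """Maximum per-lab toxicity grade increase from baseline.

    For each laboratory value the increase is ``max(followup - baseline, 0)``
    (improvement never offsets worsening elsewhere); the result is the
    maximum increase over the panel.
    """
    if set(baseline) != set(followup):
        raise ValueError("baseline and follow-up panels must cover the same labs")
    if not baseline:
        return 0
    change = 0
    for lab, base in baseline.items():
        for g in (base, followup[lab]):
            if not 0 <= int(g) <= 4:
                raise ValueError(f"grade for {lab} outside 0-4: {g}")
        change = max(change, max(int(followup[lab]) - int(base), 0))
    return change


def reild_band_summary(records) -> dict:
    """REILD incidence by cumulative functional-liver dose band.

    Cumulative dose = D_FL_TOT + prior mean liver dose.  Bands: < 30 Gy
    (strict), 30 - 60 Gy (closed), > 60 Gy (strict).  An empty band reports
    incidence ``None`` rather than zero.
    """
    bands = {"lt30": [], "30to60": [], "gt60": []}
    for rec in records:
        cum = rec.cumulative_fl_dose
        if cum < FL_DOSE_SAFE_GY:
            key = "lt30"
        elif cum > FL_DOSE_HIGH_RISK_GY:
            key = "gt60"
        else:
            key = "30to60"
        bands[key].append(bool(rec.reild))
    out = {}
    for key, flags in bands.items():
        n = len(flags)
        k = sum(flags)
        out[key] = {
            "n": n,
            "reild": k,
            "incidence_percent": None if n == 0 else 100.0 * k / n,
        }
    return out


# ---------------------------------------------------------------------------
# cohort table I/O

#: Column dictionary for cohort CSV tables (records_to_frame order).
COHORT_COLUMNS = {
    "cell_type": "tumour cell type (HCC/CCA/NET/CRC/other)",
    "d_t_gy": "tumour absorbed dose D_T (Gy)",
    "d_fl_tot_gy": "functional-liver absorbed dose D_FL_TOT (Gy)",
    "prior_liver_dose_gy": "mean liver dose from prior radiation (Gy)",
    "response_3m": "RECIST/mRECIST label at 3 months",
    "response_6m": "RECIST/mRECIST label at 6 months",
    "baseline_grades": "baseline CTCAE grades, 'lab:grade;...'",
    "max_followup_grades": "maximum follow-up CTCAE grades, 'lab:grade;...'",
    "reild": "radioembolization-induced liver disease (0/1)",
    "survival_months": "survival from treatment (months)",
    "event": "death observed (1) or censored (0)",
}


def _encode_grades(grades: dict) -> str:
    return ";".join(f"{lab}:{int(g)}" for lab, g in sorted(grades.items()))


def _decode_grades(text) -> dict:
    if not isinstance(text, str) or not text:
        return {}
    return {lab: int(g) for lab, g in (item.split(":") for item in text.split(";"))}


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "cell_type": r.cell_type,
            "d_t_gy": r.d_t,
            "d_fl_tot_gy": r.d_fl_tot,
            "prior_liver_dose_gy": r.prior_liver_dose,
            "response_3m": r.response_3m,
            "response_6m": r.response_6m,
            "baseline_grades": _encode_grades(r.baseline_grades),
            "max_followup_grades": _encode_grades(r.max_followup_grades),
            "reild": int(r.reild),
            "survival_months": r.survival_months,
            "event": int(r.event),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list:
    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientRecord(
                cell_type=row["cell_type"],
                d_t=float(row["d_t_gy"]),
                d_fl_tot=float(row["d_fl_tot_gy"]),
                prior_liver_dose=float(row.get("prior_liver_dose_gy", 0.0)),
                response_3m=str(row.get("response_3m", "not_evaluable")),
                response_6m=str(row.get("response_6m", "not_evaluable")),
                baseline_grades=_decode_grades(row.get("baseline_grades", "")),
                max_followup_grades=_decode_grades(row.get("max_followup_grades", "")),
                reild=bool(int(row.get("reild", 0))),
                survival_months=float(row.get("survival_months", 0.0)),
                event=bool(int(row.get("event", 0))),
            )
        )
    return records


def load_outcome_counts() -> pd.DataFrame:
    """Packaged per-cell-type outcome counts of the validation cohort.

    Columns: responders/evaluable at 3 and 6 months, grade 3/4 toxicity
    counts, and REILD counts, one row per tumour cell type.
    """
    with importlib.resources.files("hepadose.data").joinpath("outcome_counts.csv").open() as fh:
        return pd.read_csv(fh)


def response_table_from_counts(frame: pd.DataFrame, timepoint: str) -> ResponseTable:
    """Build a ResponseTable from the packaged outcome-count frame.

    ``timepoint`` is ``"3m"`` or ``"6m"``.
    """
    if timepoint not in ("3m", "6m"):
        raise ValueError("timepoint must be '3m' or '6m'")
    groups = {
        row["cell_type"]: (int(row[f"responders_{timepoint}"]), int(row[f"evaluable_{timepoint}"]))
        for _, row in frame.iterrows()
    }
    return ResponseTable(groups=groups)
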