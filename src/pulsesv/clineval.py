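"""Clinical-style evaluation: repeat averaging, hemodynamic-coherence
filtering, and agreement statistics.

Patient tables carry measurements from two settings: the PWV assessment
(cuff SBP/DBP/HR repeats plus two cfPWV readings) and the
catheterization laboratory (cuff repeats plus thermodilution cardiac
output and heart rate, from which the reference stroke volume is
SV = CO/HR). Patients whose MAP or HR differ between settings by more
than a relative threshold (default 25%) are excluded as hemodynamically
incoherent. Agreement between predicted and reference stroke volume is
summarized by Pearson correlation, MAE, RMSE, range-normalized RMSE and
Bland-Altman bias with 95% limits of agreement, plus a Wilcoxon
signed-rank test for a systematic paired difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COHERENCE_THRESHOLD = 0.25

_REPEAT_FIELDS = {
    "sbp_pwv": 3, "dbp_pwv": 3, "hr_pwv": 3,
    "sbp_cath": 3, "dbp_cath": 3, "hr_cath": 3,
    "pwv": 2,
}


@dataclass
class PatientRecord:
    """Raw repeated measurements of one patient at both settings.

    Repeat lists may hold 1..3 values (1..2 for cfPWV); missing repeats
    are simply absent. Thermodilution CO is in L/min.
    """

    id: str
    age_group: str
    gender: str
    height: float
    weight: float
    sbp_pwv: list[float]
    dbp_pwv: list[float]
    hr_pwv: list[float]
    pwv: list[float]
    sbp_cath: list[float]
    dbp_cath: list[float]
    hr_cath: list[float]
    co_thermo_lmin: float

    def validate(self) -> None:
        for name, _max in _REPEAT_FIELDS.items():
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"patient {self.id}: no repeats for {name}")
            if len(vals) > _max:
                raise ValueError(
                    f"patient {self.id}: too many repeats for {name}"
                )
        if any(v <= 0 for v in self.pwv):
            raise ValueError(f"patient {self.id}: non-positive cfPWV reading")
        if self.co_thermo_lmin <= 0:
            raise ValueError(f"patient {self.id}: non-positive thermodilution CO")


@dataclass
class AveragedPatient:
    """Per-setting means of the repeated measurements plus derived values.

    MAP is computed from the averaged cuff values as DBP + PP/3;
    sv_reference = thermodilution CO (L/min) * 1000 / catheterization HR.
    """

    id: str
    age_group: str
    gender: str
    height: float
    weight: float
    sbp_pwv: float
    dbp_pwv: float
    pp_pwv: float
    map_pwv: float
    hr_pwv: float
    cfpwv: float
    sbp_cath: float
    dbp_cath: float
    pp_cath: float
    map_cath: float
    hr_cath: float
    sv_reference: float


@dataclass
class AgreementReport:
    n: int
    pearson_r: float
    p_value_r: float
    mae: float
    rmse: float
    nrmse: float
    bias: float
    loa_low: float
    loa_high: float
    wilcoxon_p: float
    mean_reference: float
    sd_reference: float
    mean_predicted: float
    sd_predicted: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f.name: [getattr(self, f.name)] for f in fields(self)}
        )

    def summary(self) -> str:
        return (
            f"n = {self.n}\n"
            f"Pearson r = {self.pearson_r:.3f} (p = {self.p_value_r:.3g})\n"
            f"MAE = {self.mae:.1f} mL, RMSE = {self.rmse:.1f} mL, "
            f"nRMSE = {100 * self.nrmse:.1f}%\n"
            f"Bland-Altman bias = {self.bias:.1f} mL, "
            f"LoA = [{self.loa_low:.1f}, {self.loa_high:.1f}] mL\n"
            f"Wilcoxon signed-rank p = {self.wilcoxon_p:.3g}\n"
            f"reference {self.mean_reference:.0f} +/- {self.sd_reference:.0f} mL, "
            f"predicted {self.mean_predicted:.0f} +/- {self.sd_predicted:.0f} mL"
        )


@dataclass
class CoherenceDiagnostics:
    kept: list[AveragedPatient]
    excluded: list[AveragedPatient]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def average_repeats(record: PatientRecord) -> AveragedPatient:
    """Arithmetic means over the available repeats per setting (a single
    repeat is tolerated, with a log note via diagnostics downstream)."""
    record.validate()
    m = {name: float(np.mean(getattr(record, name))) for name in _REPEAT_FIELDS}
    pp_pwv = m["sbp_pwv"] - m["dbp_pwv"]
    pp_cath = m["sbp_cath"] - m["dbp_cath"]
    return AveragedPatient(
        id=record.id,
        age_group=record.age_group,
        gender=record.gender,
        height=record.height,
        weight=record.weight,
        sbp_pwv=m["sbp_pwv"],
        dbp_pwv=m["dbp_pwv"],
        pp_pwv=pp_pwv,
        map_pwv=m["dbp_pwv"] + pp_pwv / 3.0,
        hr_pwv=m["hr_pwv"],
        cfpwv=m["pwv"],
        sbp_cath=m["sbp_cath"],
        dbp_cath=m["dbp_cath"],
        pp_cath=pp_cath,
        map_cath=m["dbp_cath"] + pp_cath / 3.0,
        hr_cath=m["hr_cath"],
        sv_reference=record.co_thermo_lmin * 1000.0 / m["hr_cath"],
    )


def coherence_filter(
    patients: list[AveragedPatient],
    threshold: float = DEFAULT_COHERENCE_THRESHOLD,
) -> CoherenceDiagnostics:
    """Partition patients by hemodynamic coherence between settings.

    A patient is excluded iff the relative difference of MAP or of HR,
    |x_pwv - x_cath| / x_cath, exceeds the threshold. Returns disjoint,
    exhaustive partitions with a per-patient diagnostic table.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept: list[AveragedPatient] = []
    excluded: list[AveragedPatient] = []
    rows = []
    for p in patients:
        d_map = abs(p.map_pwv - p.map_cath) / p.map_cath
        d_hr = abs(p.hr_pwv - p.hr_cath) / p.hr_cath
        out = d_map > threshold or d_hr > threshold
        rows.append(
            {
                "id": p.id,
                "rel_diff_map": d_map,
                "rel_diff_hr": d_hr,
                "excluded": out,
            }
        )
        (excluded if out else kept).append(p)
    return CoherenceDiagnostics(
        kept=kept, excluded=excluded, table=pd.DataFrame(rows)
    )


def agreement(reference, predicted) -> AgreementReport:
    """Agreement statistics between a reference and a predicted series.

    Bias = mean(predicted - reference); LoA = bias +/- 1.96 * SD of the
    differences (population SD); nRMSE = RMSE / (max - min) of the
    reference. Wilcoxon uses the exact null for n < 25, otherwise the
    continuity-corrected normal approximation. For identical series the
    correlation degenerates to r = 1 with zero-width limits.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("series must be equal-length 1-D")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(ref).all() and np.isfinite(pred).all()):
        raise ValueError("non-finite values in input series")
    rng_ref = ref.max() - ref.min()
    if rng_ref == 0:
        raise ValueError("zero reference range: nRMSE undefined")
    diff = pred - ref
    if np.allclose(diff, 0.0) and np.ptp(pred) > 0:
        r, p_r = 1.0, 0.0
    else:
        r, p_r = stats.pearsonr(ref, pred)
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=0))
    if np.allclose(diff, 0.0):
        wilcoxon_p = 1.0
    else:
        mode = "exact" if n < 25 else "approx"
        wilcoxon_p = float(
            stats.wilcoxon(pred, ref, correction=True, method=mode).pvalue
        )
    return AgreementReport(
        n=n,
        pearson_r=float(r),
        p_value_r=float(p_r),
        mae=float(np.abs(diff).mean()),
        rmse=rmse,
        nrmse=rmse / rng_ref,
        bias=bias,
        loa_low=bias - 1.96 * sd_diff,
        loa_high=bias + 1.96 * sd_diff,
        wilcoxon_p=wilcoxon_p,
        mean_reference=float(ref.mean()),
        sd_reference=float(ref.std(ddof=1)),
        mean_predicted=float(pred.mean()),
        sd_predicted=float(pred.std(ddof=1)),
    )


_SETTING_QUANTITIES = {
    "sbp": ("sbp_pwv", "sbp_cath"),
    "dbp": ("dbp_pwv", "dbp_cath"),
    "map": ("map_pwv", "map_cath"),
    "hr": ("hr_pwv", "hr_cath"),
}


def compare_settings(patients: list[AveragedPatient]) -> pd.DataFrame:
    """Paired comparison of SBP/DBP/MAP/HR between the PWV-assessment and
    catheterization settings: paired-t p-value, mean absolute difference
    +/- SD and its min-max range. Identical settings give a NaN paired-t
    p-value (zero-variance differences), by convention."""
    if len(patients) < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for name, (a, b) in _SETTING_QUANTITIES.items():
        x = np.array([getattr(p, a) for p in patients], dtype=float)
        y = np.array([getattr(p, b) for p in patients], dtype=float)
        absdiff = np.abs(x - y)
        if np.ptp(x - y) == 0 and absdiff[0] == 0:
            p_t = np.nan
        else:
            p_t = float(stats.ttest_rel(x, y).pvalue)
        rows.append(
            {
                "quantity": name,
                "mean_pwv": x.mean(),
                "mean_cath": y.mean(),
                "paired_t_p": p_t,
                "mean_abs_diff": absdiff.mean(),
                "sd_abs_diff": absdiff.std(ddof=1) if len(absdiff) > 1 else 0.0,
                "min_abs_diff": absdiff.min(),
                "max_abs_diff": absdiff.max(),
            }
        )
    return pd.DataFrame(rows)


def cohort_vs_population_tests(cohort_feature, patient_feature):
    """Welch's unequal-variance t-test between the synthetic cohort and a
    patient series (handles very different sample sizes)."""
    a = np.asarray(cohort_feature, dtype=float)
    b = np.asarray(patient_feature, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both series need at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero variance in both series")
    return stats.ttest_ind(a, b, equal_var=False)


def features_from_patients(
    patients: list[AveragedPatient],
    age_midpoints: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Estimator feature table from averaged patients.

    Uses the PWV-assessment BP values (the setting that matches
    non-invasive practice, and the one the cfPWV was acquired in) and
    the stratum-midpoint age encoding.
    """
    if age_midpoints is None:
        from .population import load_population_spec

        age_midpoints = load_population_spec().age_midpoints
    rows = []
    for p in patients:
        rows.append(
            {
                "age": age_midpoints[p.age_group],
                "gender": p.gender,
                "weight": p.weight,
                "height": p.height,
                "sbp": p.sbp_pwv,
                "dbp": p.dbp_pwv,
                "pp": p.pp_pwv,
                "map": p.map_pwv,
                "cfpwv": p.cfpwv,
                "id": p.id,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient-table CSV dialect

def _repeat_cols() -> list[str]:
    cols = []
    for name, k in _REPEAT_FIELDS.items():
        cols.extend(f"{name}_{i + 1}" for i in range(k))
    return cols


PATIENT_TABLE_COLUMNS = [
    "id", "age_group", "gender", "height", "weight", *_repeat_cols(),
    "co_thermo_lmin",
]


def patients_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age_group": r.age_group,
            "gender": r.gender,
            "height": r.height,
            "weight": r.weight,
            "co_thermo_lmin": r.co_thermo_lmin,
        }
        for name, k in _REPEAT_FIELDS.items():
            vals = getattr(r, name)
            for i in range(k):
                row[f"{name}_{i + 1}"] = vals[i] if i < len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=PATIENT_TABLE_COLUMNS)


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in PATIENT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "id": str(row["id"]),
            "age_group": str(row["age_group"]),
            "gender": str(row["gender"]),
            "height": float(row["height"]),
            "weight": float(row["weight"]),
            "co_thermo_lmin": float(row["co_thermo_lmin"]),
        }
        for name, k in _REPEAT_FIELDS.items():
            vals = [
                float(row[f"{name}_{i + 1}"])
                for i in range(k)
                if np.isfinite(row[f"{name}_{i + 1}"])
            ]
            kwargs[name] = vals
        records.append(PatientRecord(**kwargs))
    return records


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    return frame_to_patients(pd.read_csv(path))


def write_patient_table(records: list[PatientRecord], path: str | Path) -> None:
    patients_to_frame(records).to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# plots


def bland_altman_plot(reference, predicted, path: str | Path) -> None:
    """Bland-Altman plot (difference vs mean) with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    rep = agreement(ref, pred)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
    ax = axes[0]
    lims = [min(ref.min(), pred.min()) - 5, max(ref.max(), pred.max()) + 5]
    ax.scatter(ref, pred, s=22, alpha=0.8)
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("reference SV (mL)")
    ax.set_ylabel("predicted SV (mL)")
    ax.set_title(f"r = {rep.pearson_r:.2f}, MAE = {rep.mae:.1f} mL")
    ax = axes[1]
    ax.scatter((ref + pred) / 2, pred - ref, s=22, alpha=0.8)
    for y, style in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of reference and predicted SV (mL)")
    ax.set_ylabel("predicted - reference (mL)")
    ax.set_title(
        f"bias {rep.bias:.1f} mL, LoA [{rep.loa_low:.1f}, {rep.loa_high:.1f}]"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
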