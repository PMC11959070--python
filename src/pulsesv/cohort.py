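"""Synthetic hemodynamic cohort generation.

Pipeline per subject: draw (height, weight, HR, aortic distensibility,
TPR, MAP) from the stratified population spec; derive cardiac output
CO = MAP/TPR, stroke volume SV = CO/HR and ejection time from the
Weissler regression; scale the reference arterial tree to the subject
(lengths by height, diameters by a predicted aortic diameter,
distensibilities/compliances by the aortic-distensibility ratio,
terminal resistances to the sampled TPR); run the 1-D simulation; and
extract the estimator features (brachial SBP/DBP/PP/MAP and
carotid-femoral PWV) from the simulated waveforms. The feature target
``sv`` is the imposed inflow volume, never re-derived from waveforms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arterial1d import (
    ArterialTree,
    SolverConfig,
    SolverError,
    solve,
    synthesize_inflow,
)
from .population import PARAMETERS, PopulationSpec
from .wavefeat import (
    PressureWaveform,
    WaveformError,
    cfpwv,
    extract_bp_features,
    transit_time,
)

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "age", "gender", "weight", "height", "sbp", "dbp", "pp", "map", "cfpwv",
]
DATASET_COLUMNS = FEATURE_COLUMNS + ["sv"]

REFERENCE_HEIGHT_CM = 180.0


def default_aortic_model_path() -> Path:
    return Path(__file__).resolve().parent / "data" / "aortic_diameter.yaml"


@dataclass
class SubjectProfile:
    """One sampled synthetic individual and its derived quantities."""

    age_group: str
    gender: str
    height: float
    weight: float
    heart_rate: float
    aortic_distensibility: float
    tpr: float
    map_target: float
    co: float = 0.0            # mL/s
    sv: float = 0.0            # mL
    ejection_time: float = 0.0  # s
    length_scale: float = 1.0
    diameter_scale: float = 1.0
    distensibility_scale: float = 1.0
    resistance_scale: float = 1.0

    @property
    def co_l_min(self) -> float:
        return self.co * 0.06


@dataclass(frozen=True)
class FeatureRecord:
    """The 9 estimator inputs plus the stroke-volume target."""

    age: float
    gender: str
    weight: float
    height: float
    sbp: float
    dbp: float
    pp: float
    map: float
    cfpwv: float
    sv_true: float


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: int = 833
    seed: int = 0
    truncation_rule: str = "three_sigma_positive"

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.truncation_rule != "three_sigma_positive":
            raise ValueError(
                "only the 'three_sigma_positive' truncation rule is implemented"
            )


# ---------------------------------------------------------------------------
# derived boundary-condition quantities


def derive_flow(
    map_target: float, tpr: float, heart_rate: float
) -> tuple[float, float]:
    """CO and SV from mean pressure and total peripheral resistance.

    CO = MAP/TPR (mL/s, since TPR is in mmHg*s/mL); SV = CO per beat,
    i.e. CO * 60/HR (mL). CO in L/min is co * 0.06.
    """
    if map_target <= 0 or tpr <= 0 or heart_rate <= 0:
        raise ValueError("MAP, TPR and HR must all be positive")
    co = map_target / tpr
    sv = co * 60.0 / heart_rate
    return co, sv


def weissler_ejection_time(sv: float, heart_rate: float) -> float:
    """Left-ventricular ejection time (s) from the Weissler regression,

        ET = 0.266 + 0.0011*(SV - 82) - 0.0009*(HR - 73),

    clamped to (0.05 s, 0.95*period) with a logged warning when the raw
    value leaves that admissible window.
    """
    if sv <= 0 or heart_rate <= 0:
        raise ValueError("SV and HR must be positive")
    et = 0.266 + 0.0011 * (sv - 82.0) - 0.0009 * (heart_rate - 73.0)
    lo, hi = 0.05, 0.95 * 60.0 / heart_rate
    if not lo < et < hi:
        clamped = min(max(et, lo), hi)
        logger.warning(
            "ejection time %.4f s outside (%.3f, %.3f); clamped to %.4f",
            et, lo, hi, clamped,
        )
        return clamped
    return et


def length_scale_factor(height: float) -> float:
    """Uniform segment-length scaling: height relative to the 180 cm
    reference subject (e.g. 170 cm -> 0.94)."""
    if height <= 0:
        raise ValueError("height must be positive")
    return height / REFERENCE_HEIGHT_CM


def bsa_dubois(weight: float, height: float) -> float:
    """Du Bois body surface area (m^2) from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def _load_aortic_model(model_coeffs) -> dict:
    if model_coeffs is None:
        model_coeffs = default_aortic_model_path()
    if isinstance(model_coeffs, (str, Path)):
        with open(model_coeffs) as fh:
            model_coeffs = yaml.safe_load(fh)
    for key in ("intercept", "age_slope", "bsa_slope", "reference"):
        if key not in model_coeffs:
            raise ValueError(f"aortic-diameter model missing {key!r}")
    return model_coeffs


def _aortic_diameter(model: dict, gender: str, age: float, bsa: float) -> float:
    return (
        float(model["intercept"][gender])
        + float(model["age_slope"]) * age
        + float(model["bsa_slope"]) * bsa
    )


def diameter_scale_factor(
    age_group: str,
    gender: str,
    weight: float,
    height: float,
    model_coeffs: dict | str | Path | None = None,
    age_midpoints: dict[str, float] | None = None,
) -> float:
    """Uniform diameter scaling from a linear aortic-diameter model in
    age, gender and body surface area, relative to the model's reference
    subject."""
    model = _load_aortic_model(model_coeffs)
    if age_midpoints is None:
        from .population import load_population_spec

        age_midpoints = load_population_spec().age_midpoints
    age = (
        age_midpoints[age_group]
        if age_group in age_midpoints
        else float(age_group)
    )
    ref = model["reference"]
    d = _aortic_diameter(model, gender, age, bsa_dubois(weight, height))
    d_ref = _aortic_diameter(
        model,
        ref["gender"],
        float(ref["age"]),
        bsa_dubois(float(ref["weight"]), float(ref["height"])),
    )
    return d / d_ref


# ---------------------------------------------------------------------------
# sampling


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, n: int
) -> np.ndarray:
    """Gaussian draws redrawn until inside [max(mean-3sd, floor), mean+3sd]."""
    lo = max(mean - 3.0 * sd, floor)
    hi = mean + 3.0 * sd
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_profiles(
    spec: PopulationSpec, config: CohortConfig
) -> list[SubjectProfile]:
    """Draw ``n_per_group`` subjects per stratum (independent Gaussians
    per parameter, no inter-parameter correlation), deterministic in the
    seed."""
    rng = np.random.default_rng(config.seed)
    aortic_model = _load_aortic_model(None)
    profiles: list[SubjectProfile] = []
    for age_group, gender in spec.stratum_labels:
        draws = {
            p: _truncated_normal(
                rng,
                *spec.mean_sd(age_group, gender, p),
                spec.floors.get(p, 0.0),
                config.n_per_group,
            )
            for p in PARAMETERS
        }
        for i in range(config.n_per_group):
            prof = SubjectProfile(
                age_group=age_group,
                gender=gender,
                height=draws["height"][i],
                weight=draws["weight"][i],
                heart_rate=draws["heart_rate"][i],
                aortic_distensibility=draws["aortic_distensibility"][i],
                tpr=draws["tpr"][i],
                map_target=draws["map"][i],
            )
            prof.co, prof.sv = derive_flow(
                prof.map_target, prof.tpr, prof.heart_rate
            )
            prof.ejection_time = weissler_ejection_time(
                prof.sv, prof.heart_rate
            )
            prof.length_scale = length_scale_factor(prof.height)
            prof.diameter_scale = diameter_scale_factor(
                age_group, gender, prof.weight, prof.height,
                model_coeffs=aortic_model,
                age_midpoints=spec.age_midpoints,
            )
            profiles.append(prof)
    return profiles


def apply_subject_scaling(
    tree: ArterialTree, profile: SubjectProfile
) -> ArterialTree:
    """Return a copy of ``tree`` adjusted to the subject.

    Lengths scale by height/reference height; diameters by the aortic-
    diameter ratio; segment distensibilities and terminal compliances by
    the sampled-to-reference aortic-distensibility ratio; and all
    terminal resistances by a common factor chosen so their parallel
    combination equals the sampled TPR. The input tree is not modified;
    the applied factors are recorded on the profile.
    """
    if profile.tpr <= 0:
        raise ValueError("sampled TPR must be positive")
    profile.distensibility_scale = (
        profile.aortic_distensibility / tree.reference_aortic_distensibility
    )
    profile.resistance_scale = profile.tpr / tree.total_peripheral_resistance()
    return tree.with_scaled(
        length_factor=profile.length_scale,
        diameter_factor=profile.diameter_scale,
        distensibility_factor=profile.distensibility_scale,
        resistance_factor=profile.resistance_scale,
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortResult:
    dataset: pd.DataFrame
    n_requested: int
    n_dropped: int
    dropped: list[tuple[str, str, str]] = field(default_factory=list)


def simulate_subject(
    tree: ArterialTree,
    profile: SubjectProfile,
    solver_config: SolverConfig | None = None,
) -> FeatureRecord:
    """Scale the tree to one subject, simulate, and extract features.

    Raises :class:`SolverError` if the simulation blows up or fails to
    reach cycle periodicity.
    """
    scaled = apply_subject_scaling(tree, profile)
    inflow = synthesize_inflow(
        profile.sv, profile.heart_rate, profile.ejection_time
    )
    result = solve(scaled, inflow, config=solver_config)
    if not result.converged:
        raise SolverError("simulation did not reach cycle periodicity")
    bp = extract_bp_features(
        PressureWaveform(
            result.time, result.pressure["left_brachial"], result.period, 1
        )
    )
    tt = transit_time(
        PressureWaveform(
            result.time, result.pressure["carotid"], result.period, 1
        ),
        PressureWaveform(
            result.time, result.pressure["femoral"], result.period, 1
        ),
        min_cycles=1,
    )
    path = scaled.path_length("carotid", "femoral")
    return FeatureRecord(
        age=0.0,  # filled by the caller from the stratum midpoint
        gender=profile.gender,
        weight=profile.weight,
        height=profile.height,
        sbp=bp.sbp,
        dbp=bp.dbp,
        pp=bp.pp,
        map=bp.map,
        cfpwv=cfpwv(path, tt.mean_delta_t),
        sv_true=profile.sv,
    )


def generate_cohort(
    spec: PopulationSpec,
    tree: ArterialTree,
    solver_config: SolverConfig | None = None,
    cohort_config: CohortConfig | None = None,
    out_path: str | Path | None = None,
    max_drop_fraction: float = 0.2,
) -> CohortResult:
    """Sample, simulate and assemble the training dataset.

    Non-converged simulations and degenerate waveform extractions are
    dropped with a logged count;
    more than ``max_drop_fraction`` failures within any stratum aborts
    with a diagnostic. When ``out_path`` is given, the dataset is written
    as CSV with a JSON metadata sidecar (seed, n_per_group, config hash).
    """
    cohort_config = cohort_config or CohortConfig()
    profiles = sample_profiles(spec, cohort_config)
    rows: list[dict] = []
    dropped: list[tuple[str, str, str]] = []
    drop_count: dict[tuple[str, str], int] = {}
    for prof in profiles:
        try:
            rec = simulate_subject(tree, prof, solver_config)
        except (SolverError, WaveformError) as exc:
            key = (prof.age_group, prof.gender)
            drop_count[key] = drop_count.get(key, 0) + 1
            dropped.append((prof.age_group, prof.gender, str(exc)))
            if drop_count[key] > max_drop_fraction * cohort_config.n_per_group:
                raise RuntimeError(
                    f"stratum {key}: more than {max_drop_fraction:.0%} of "
                    f"simulations failed ({drop_count[key]} of "
                    f"{cohort_config.n_per_group}); last error: {exc}"
                ) from exc
            continue
        rows.append(
            {
                "age": spec.age_midpoints[prof.age_group],
                "gender": prof.gender,
                "weight": rec.weight,
                "height": rec.height,
                "sbp": rec.sbp,
                "dbp": rec.dbp,
                "pp": rec.pp,
                "map": rec.map,
                "cfpwv": rec.cfpwv,
                "sv": rec.sv_true,
            }
        )
    if dropped:
        logger.info("dropped %d non-converged simulations", len(dropped))
    dataset = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    result = CohortResult(
        dataset=dataset,
        n_requested=len(profiles),
        n_dropped=len(dropped),
        dropped=dropped,
    )
    if out_path is not None:
        write_dataset(result, cohort_config, out_path)
    return result


def config_hash(cohort_config: CohortConfig) -> str:
    payload = json.dumps(
        {
            "n_per_group": cohort_config.n_per_group,
            "seed": cohort_config.seed,
            "truncation_rule": cohort_config.truncation_rule,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_dataset(
    result: CohortResult, cohort_config: CohortConfig, out_path: str | Path
) -> None:
    out_path = Path(out_path)
    result.dataset.to_csv(out_path, index=False, float_format="%.6f")
    sidecar = out_path.with_suffix(out_path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "seed": cohort_config.seed,
                "n_per_group": cohort_config.n_per_group,
                "truncation_rule": cohort_config.truncation_rule,
                "config_hash": config_hash(cohort_config),
                "n_rows": int(len(result.dataset)),
                "n_dropped": result.n_dropped,
            },
            indent=2,
        )
    )


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    return df
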