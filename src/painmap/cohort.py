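"""Synthetic chronic low-back-pain cohort with known ground truth.

The generator emulates the study conditions end to end: 23 patients, each
with a pain-site coordinate (cm from the top of the EMG sheet), a pain
intensity (NRS 1-10) and 22 SF-MPQ-2 item scores, and per patient one
suppression-free reference trial plus three experimental trials of
band-limited (10-400 Hz) amplitude-modulated Gaussian EMG noise on the
bilateral 4-channel grids.

The encoded mechanism is motor adaptation near the painful site: each
patient's experimental trials are generated with a spatial suppression
kernel centred at the pain site,

    w(y) = A * (1 - s * exp(-(y - y_pain)^2 / (2 * width^2))),

where the suppression fraction s is a linear, clipped function of the
patient's pain-quality scores (``effect_coefficients``). With all effect
coefficients zero the activity profile is flat and every downstream effect
estimate should be indistinguishable from zero; with positive coefficients,
activity drops near the pain site, lowering extension-phase activity and
pushing the activity centroid away from the pain site. ``s`` is stored per
patient as ``true_suppression`` for recovery tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import sfmpq2
from .geometry import (
    DEFAULT_SAMPLING_RATE_HZ,
    N_PHASES,
    PHASE_DURATION_S,
    ElectrodeGrid,
    EMGRecording,
    default_grid_pair,
)
from .processing import bandpass_filter, segment_phases

#: Default marginal means/SDs of the simulated item scores (0-10 NRS each),
#: chosen to resemble a typical chronic low-back-pain outpatient cohort:
#: dull continuous qualities (heavy, aching) common, neuropathic qualities
#: (hot-burning, light touch) rare and strongly right-skewed.
DEFAULT_ITEM_MEANS: dict[str, float] = {
    "throbbing": 1.8, "cramping": 2.1, "gnawing": 0.7, "aching": 1.8,
    "heavy": 3.4, "tenderness": 1.6,
    "shooting": 1.8, "stabbing": 0.6, "sharp": 1.7, "splitting": 0.3,
    "electric_shock": 1.9, "piercing": 0.3,
    "hot_burning": 0.2, "cold_freezing": 0.8, "light_touch": 0.5,
    "itching": 0.6, "tingling_pins_needles": 0.8, "numbness": 2.6,
    "tiring_exhausting": 2.0, "sickening": 1.2, "fearful": 1.0,
    "punishing_cruel": 1.3,
}

DEFAULT_ITEM_SDS: dict[str, float] = {
    "throbbing": 2.5, "cramping": 3.0, "gnawing": 1.5, "aching": 2.5,
    "heavy": 2.9, "tenderness": 2.9,
    "shooting": 2.6, "stabbing": 1.1, "sharp": 2.5, "splitting": 1.0,
    "electric_shock": 2.9, "piercing": 0.8,
    "hot_burning": 0.6, "cold_freezing": 1.6, "light_touch": 1.1,
    "itching": 2.0, "tingling_pins_needles": 1.3, "numbness": 2.6,
    "tiring_exhausting": 2.6, "sickening": 2.0, "fearful": 2.0,
    "punishing_cruel": 2.2,
}

#: Default suppression drivers: neuropathic quality is the main driver of
#: the near-pain-site motor adaptation, with a smaller intermittent-pain
#: contribution. Subclass scores (sums of 6 items) enter s = sum(c_k * score_k)/10.
DEFAULT_EFFECT_COEFFICIENTS: dict[str, float] = {
    "neuropathic_pain": 0.4,
    "intermittent_pain": 0.2,
}

#: Relative EMG amplitude per task phase (standing, flexion, full flexion,
#: extension). Standing holds a modest postural level, flexion is eccentric
#: work, full flexion shows flexion-relaxation, extension is the agonist
#: (concentric) phase used for normalization.
DEFAULT_PHASE_FACTORS: tuple[float, float, float, float] = (0.4, 0.8, 0.3, 1.0)

MAX_SUPPRESSION = 0.95


@dataclass
class CohortConfig:
    """Simulator parameters; the defaults define the study conditions."""

    n_patients: int = 23
    n_trials: int = 3
    pain_site_mean_cm: float = 15.0
    pain_site_sd_cm: float = 7.3
    nrs_mean: float = 4.7
    nrs_sd: float = 2.1
    item_score_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_MEANS)
    )
    item_score_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_SDS)
    )
    zero_inflation: float = 0.5
    effect_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_COEFFICIENTS)
    )
    suppression_width_cm: float = 5.0
    baseline_amplitude: float = 1.0
    phase_amplitude_factors: tuple[float, float, float, float] = DEFAULT_PHASE_FACTORS
    noise_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.pain_site_sd_cm <= 0 or self.nrs_sd <= 0:
            raise ValueError("pain_site_sd_cm and nrs_sd must be > 0")
        if self.suppression_width_cm <= 0:
            raise ValueError("suppression_width_cm must be > 0")
        if len(self.phase_amplitude_factors) != N_PHASES or any(
            f <= 0 for f in self.phase_amplitude_factors
        ):
            raise ValueError(f"phase_amplitude_factors must be {N_PHASES} values > 0")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        missing = [i for i in sfmpq2.ITEM_NAMES if i not in self.item_score_means]
        if missing:
            raise ValueError(f"item_score_means missing items: {missing}")
        for name, m in self.item_score_means.items():
            sfmpq2.canonical_item(name)
            if not 0 <= m <= 10:
                raise ValueError(f"item mean {name}={m} outside [0, 10]")
        for name in self.effect_coefficients:
            sfmpq2.canonical_item(name)  # raises on unknown names


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient's pain profile plus generator ground truth."""

    patient_id: str
    pain_site_cm: float
    nrs: int
    sfmpq2_items: dict[str, int]
    true_suppression: float

    @property
    def scores(self) -> sfmpq2.SFMPQ2Scores:
        return sfmpq2.score_sfmpq2(self.sfmpq2_items)


@dataclass
class SyntheticCohort:
    """All patients and recordings of one simulated study.

    ``recordings`` is keyed by (patient_id, trial_id); trial 0 is the
    suppression-free reference trial, trials 1..n_trials are experimental.
    """

    patients: list[PatientProfile]
    recordings: dict[tuple[str, int], EMGRecording]
    ground_truth: CohortConfig


def _score_value(profile_items: Mapping[str, int], nrs: int, name: str) -> float:
    key = sfmpq2.canonical_item(name)
    if key in profile_items:
        return float(profile_items[key])
    if key in sfmpq2.SUBCLASSES:
        return float(sum(profile_items[i] for i in sfmpq2.SUBCLASSES[key]))
    raise KeyError(name)


def suppression_fraction(
    items: Mapping[str, int], nrs: int, effect_coefficients: Mapping[str, float]
) -> float:
    """Ground-truth suppression s = clip(sum_k c_k * score_k / 10, 0, 0.95).

    ``score_k`` may name an SF-MPQ-2 item or subclass (subclass score = sum
    of its items).
    """
    s = sum(
        c * _score_value(items, nrs, name) for name, c in effect_coefficients.items()
    ) / 10.0
    return float(np.clip(s, 0.0, MAX_SUPPRESSION))


def _truncated_normal_location(target_mean: float, sd: float) -> float:
    """Location mu such that a normal(mu, sd) truncated at 0 has the target mean."""

    def trunc_mean(mu: float) -> float:
        a = -mu / sd
        return mu + sd * stats.norm.pdf(a) / stats.norm.sf(a)

    lo, hi = target_mean - 6 * sd, target_mean + sd
    if trunc_mean(lo) > target_mean:  # extremely truncated regime
        lo = -50 * sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi))


def _draw_items(config: CohortConfig, rng: np.random.Generator) -> dict[str, int]:
    p0 = config.zero_inflation
    items: dict[str, int] = {}
    for name in sfmpq2.ITEM_NAMES:
        key = sfmpq2.canonical_item(name)
        if rng.random() < p0:
            items[key] = 0
            continue
        # centre the non-zero component so the marginal mean stays on target
        mu = config.item_score_means[name] / (1.0 - p0)
        sd = config.item_score_sds.get(name, 2.0)
        items[key] = int(np.clip(np.rint(rng.normal(mu, sd)), 0, 10))
    return items


def generate_patient_profiles(
    config: CohortConfig, rng: np.random.Generator
) -> list[PatientProfile]:
    """Draw ``n_patients`` pain profiles.

    Pain sites follow a >=0 truncated normal whose mean equals the configured
    mean exactly (the location parameter is solved for, not just set); NRS
    and item scores are rounded, clipped normals, NRS clipped to [1, 10] so
    every simulated patient meets the inclusion criterion. Deterministic
    given the random stream.
    """
    config.validate()
    if config.n_patients == 0:
        return []
    loc = _truncated_normal_location(config.pain_site_mean_cm, config.pain_site_sd_cm)
    a = (0.0 - loc) / config.pain_site_sd_cm
    sites = stats.truncnorm.rvs(
        a, np.inf, loc=loc, scale=config.pain_site_sd_cm,
        size=config.n_patients, random_state=rng,
    )
    width = len(str(config.n_patients))
    profiles = []
    for i in range(config.n_patients):
        nrs = int(np.clip(np.rint(rng.normal(config.nrs_mean, config.nrs_sd)), 1, 10))
        items = _draw_items(config, rng)
        s = suppression_fraction(items, nrs, config.effect_coefficients)
        profiles.append(
            PatientProfile(
                patient_id=f"P{i + 1:0{width}d}",
                pain_site_cm=float(sites[i]),
                nrs=nrs,
                sfmpq2_items=items,
                true_suppression=s,
            )
        )
    return profiles


def spatial_activity_profile(
    patient: PatientProfile, grid: ElectrodeGrid, config: CohortConfig
) -> np.ndarray:
    """Per-channel amplitude weights under the pain-site suppression kernel.

    w(y) = baseline * (1 - s * exp(-(y - pain_site)^2 / (2 * width^2))),
    with s the patient's ground-truth suppression fraction. All weights are
    strictly positive because s is clipped below 1.
    """
    y = grid.channel_y_cm
    s = suppression_fraction(patient.sfmpq2_items, patient.nrs, config.effect_coefficients)
    kernel = np.exp(
        -((y - patient.pain_site_cm) ** 2) / (2.0 * config.suppression_width_cm**2)
    )
    return config.baseline_amplitude * (1.0 - s * kernel)


def synthesize_trial(
    weights: np.ndarray,
    config: CohortConfig,
    grids: tuple[ElectrodeGrid, ElectrodeGrid],
    rng: np.random.Generator,
    trial_role: str = "experimental",
) -> EMGRecording:
    """Synthesize one 12-s trial of band-limited amplitude-modulated noise.

    Each channel is zero-mean Gaussian noise band-limited to 10-400 Hz and
    scaled so the expected RMS within phase p is
    ``weights[c] * phase_amplitude_factors[p] + noise_floor``. Phase windows
    are recorded in the returned recording's metadata.
    """
    weights = np.asarray(weights, dtype=float)
    left, right = grids
    n_channels = left.n_channels + right.n_channels
    if weights.shape != (n_channels,):
        raise ValueError(f"expected {n_channels} channel weights, got {weights.shape}")
    if np.any(weights < 0):
        raise ValueError("channel weights must be >= 0")
    if config.noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    fs = DEFAULT_SAMPLING_RATE_HZ
    n = round(N_PHASES * PHASE_DURATION_S * fs)
    white = rng.standard_normal((n, n_channels))
    shaped = bandpass_filter(white, fs)
    # scale to unit expected RMS using the whole-trial empirical level
    shaped /= np.std(shaped, axis=0, keepdims=True)
    samples = np.empty_like(shaped)
    rec = EMGRecording(
        samples=np.zeros((n, n_channels)),
        sampling_rate_hz=fs,
        grids=grids,
        trial_role=trial_role,
    )
    windows = segment_phases(rec)
    for p, w in enumerate(windows):
        target = weights * config.phase_amplitude_factors[p] + config.noise_floor
        samples[w.start_sample : w.end_sample] = (
            shaped[w.start_sample : w.end_sample] * target
        )
    return EMGRecording(
        samples=samples,
        sampling_rate_hz=fs,
        grids=grids,
        phase_boundaries=windows,
        trial_role=trial_role,
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic study, reproducibly from ``config.seed``.

    For each patient: one reference trial with uniform baseline weights (no
    suppression — a clean normalization denominator) and ``n_trials``
    experimental trials with pain-modulated weights.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grids = default_grid_pair()
    patients = generate_patient_profiles(config, rng)
    recordings: dict[tuple[str, int], EMGRecording] = {}
    baseline = np.full(grids[0].n_channels + grids[1].n_channels, config.baseline_amplitude)
    for patient in patients:
        recordings[(patient.patient_id, 0)] = synthesize_trial(
            baseline, config, grids, rng, trial_role="reference"
        )
        exp_weights = np.concatenate(
            [spatial_activity_profile(patient, g, config) for g in grids]
        )
        for t in range(1, config.n_trials + 1):
            recordings[(patient.patient_id, t)] = synthesize_trial(
                exp_weights, config, grids, rng, trial_role="experimental"
            )
    return SyntheticCohort(patients=patients, recordings=recordings, ground_truth=config)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study conditions with the suppression mechanism switched off.

    All effect coefficients are zero, so every patient's spatial activity
    profile is flat and downstream effect estimates should be
    indistinguishable from zero — the type-I-error / calibration condition.
    """
    overrides.setdefault("effect_coefficients", {})
    return CohortConfig(seed=seed, **overrides)


def sign_recovery_config(seed: int = 0, **overrides) -> CohortConfig:
    """Mechanism-isolation scenario: suppression driven by one item.

    Suppression is driven entirely by "pain caused by light touch"
    (coefficient 1.5, marginal item mean raised to 3 so roughly half the
    cohort carries a strong exposure), and pain sites are clustered just
    caudal of the electrode grid (mean 9.0 cm, SD 0.75 cm). At that position
    the suppression kernel displaces the activity centroid cranially by up
    to ~1.7 cm, and the small positional scatter keeps the between-patient
    DISTANCE variation mechanism-driven instead of dominated by where the
    pain happens to be. Expected directions: light-touch score negatively
    associated with extension-phase activity, positively with DISTANCE.
    """
    means = dict(DEFAULT_ITEM_MEANS)
    means["light_touch"] = 3.0
    defaults = dict(
        effect_coefficients={"light_touch": 1.5},
        item_score_means=means,
        pain_site_mean_cm=9.0,
        pain_site_sd_cm=0.75,
    )
    defaults.update(overrides)
    return CohortConfig(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# tabular views and on-disk layout


def patients_dataframe(patients: list[PatientProfile]) -> pd.DataFrame:
    """Patient table: id, pain site, NRS, 22 item columns, subclass sums,
    total, and the generator's ground-truth suppression."""
    rows = []
    for p in patients:
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "pain_site_cm": p.pain_site_cm,
            "nrs": p.nrs,
        }
        row.update({k: p.sfmpq2_items[k] for k in sfmpq2.ITEM_NAMES})
        scores = p.scores
        for sub in sfmpq2.SUBCLASS_NAMES:
            row[sub] = scores.subclass(sub)
        row["total"] = scores.total
        row["true_suppression"] = p.true_suppression
        rows.append(row)
    columns = (
        ["patient_id", "pain_site_cm", "nrs"]
        + list(sfmpq2.ITEM_NAMES)
        + list(sfmpq2.SUBCLASS_NAMES)
        + ["total", "true_suppression"]
    )
    return pd.DataFrame(rows, columns=columns)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write patient table, per-trial signal files, and the trial manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signals = outdir / "signals"
    signals.mkdir(exist_ok=True)
    patients_dataframe(cohort.patients).to_csv(
        outdir / "patients.csv", index=False, float_format="%.6g"
    )
    manifest_rows = []
    for (pid, tid), rec in sorted(cohort.recordings.items()):
        path = signals / f"{pid}_trial{tid}.csv"
        buf = io.StringIO()
        buf.write(",".join(rec.channel_names) + "\n")
        np.savetxt(buf, rec.samples, fmt="%.6g", delimiter=",")
        path.write_text(buf.getvalue())
        manifest_rows.append(
            {
                "patient_id": pid,
                "trial_id": tid,
                "role": rec.trial_role,
                "path": str(path.relative_to(outdir)),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def load_cohort(indir: str | Path) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Ground-truth generator parameters are not round-tripped; the returned
    cohort carries a default config with ``n_patients``/``n_trials`` set
    from the data.
    """
    indir = Path(indir)
    pat_df = pd.read_csv(indir / "patients.csv")
    patients = [
        PatientProfile(
            patient_id=str(r["patient_id"]),
            pain_site_cm=float(r["pain_site_cm"]),
            nrs=int(r["nrs"]),
            sfmpq2_items={k: int(r[k]) for k in sfmpq2.ITEM_NAMES},
            true_suppression=float(r.get("true_suppression", np.nan)),
        )
        for _, r in pat_df.iterrows()
    ]
    manifest = pd.read_csv(indir / "manifest.csv")
    grids = default_grid_pair()
    recordings: dict[tuple[str, int], EMGRecording] = {}
    n_trials = 1
    for _, r in manifest.iterrows():
        path = indir / str(r["path"])
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing signal file: {path}")
        try:
            samples = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"corrupt signal file {path}: {exc}") from exc
        rec = EMGRecording(
            samples=samples, grids=grids, trial_role=str(r["role"])
        )
        recordings[(str(r["patient_id"]), int(r["trial_id"]))] = rec
        n_trials = max(n_trials, int(r["trial_id"]))
    config_kwargs = dict(n_patients=len(patients), n_trials=n_trials)
    return SyntheticCohort(
        patients=patients,
        recordings=recordings,
        ground_truth=CohortConfig(**config_kwargs),
    )


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["phase_amplitude_factors"] = list(config.phase_amplitude_factors)
    return d


def config_from_dict(d: Mapping) -> CohortConfig:
    kwargs = dict(d)
    if "phase_amplitude_factors" in kwargs:
        kwargs["phase_amplitude_factors"] = tuple(kwargs["phase_amplitude_factors"])
    return CohortConfig(**kwargs)
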