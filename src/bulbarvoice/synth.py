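"""Synthetic sustained-vowel generation with known jitter, shimmer and HNR.

The clinical recordings this analysis was designed for are not public, so
every stage is exercised against synthetic phonations whose ground truth is
known exactly.  A phonation is modelled as a glottal pulse train: smooth
raised-cosine flow pulses whose onset spacing carries the injected jitter
(per-cycle period perturbation), whose per-pulse gain carries the injected
shimmer (per-cycle amplitude perturbation), optionally shaped by formant
resonators, plus white noise scaled to a target harmonics-to-noise power
ratio.  The realized per-cycle periods and amplitudes are retained on the
recording so extraction accuracy can be measured against truth.

Cohort generation emulates the study population this pipeline targets:
a control group (C), ALS with bulbar involvement (B, elevated jitter and
shimmer, depressed HNR, largest spread) and ALS without bulbar involvement
(NB, intermediate means with inflated variance), with sex-dependent F0 and
a younger control group so the aging correction has real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .recording import GROUPS, SEXES, VOWELS, VoiceRecording

# Neutral formant targets per vowel (Hz); vowel identity is irrelevant to
# the phonatory features but makes fixtures spectrally realistic.
VOWEL_FORMANTS: dict[str, tuple[float, ...]] = {
    "a": (700.0, 1100.0, 2600.0),
    "e": (400.0, 2000.0, 2600.0),
    "i": (300.0, 2300.0, 3000.0),
    "o": (450.0, 800.0, 2600.0),
    "u": (325.0, 700.0, 2530.0),
}
_FORMANT_BANDWIDTHS = (80.0, 90.0, 120.0)


def expected_perturbation(frac: float) -> float:
    """Closed-form expected relative perturbation (%) for i.i.d. Gaussian
    per-cycle perturbation with standard deviation ``frac`` x mean.

    For X_i i.i.d. N(mu, sigma^2), E|X_i - X_{i-1}| = 2 sigma / sqrt(pi),
    so the mean absolute consecutive difference divided by the mean is
    2 (sigma/mu) / sqrt(pi).  Valid in the small-perturbation regime where
    the measured mean is ~= mu (frac < 0.1).
    """
    if frac < 0:
        raise ValueError("perturbation fraction must be >= 0")
    if frac >= 0.1:
        raise ValueError("linearization only holds for frac < 0.1")
    return 100.0 * 2.0 * frac / math.sqrt(math.pi)


@dataclass
class GlottalSpec:
    """Parameters of one synthetic glottal pulse train."""

    f0_hz: float = 150.0
    duration_s: float = 3.0
    sample_rate_hz: float = 44100.0
    jitter_frac: float = 0.0      # SD of per-cycle period perturbation / mean period
    shimmer_frac: float = 0.0     # SD of per-cycle amplitude perturbation / mean amplitude
    hnr_db: float = math.inf      # harmonic-power / noise-power target, dB
    formant_freqs_hz: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f0_hz > 0:
            raise ValueError("f0_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.jitter_frac < 0 or self.shimmer_frac < 0:
            raise ValueError("jitter_frac and shimmer_frac must be >= 0")
        fmax = max(self.formant_freqs_hz) if self.formant_freqs_hz else self.f0_hz
        if self.sample_rate_hz < 4.0 * max(fmax, self.f0_hz):
            raise ValueError("sample_rate_hz must be >= 4x the highest frequency present")


def _resonator_cascade(x: np.ndarray, freqs: tuple[float, ...], fs: float) -> np.ndarray:
    """All-pole second-order resonators in cascade (formant shaping)."""
    for f, bw in zip(freqs, _FORMANT_BANDWIDTHS):
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * f / fs
        a = np.array([1.0, -2.0 * r * math.cos(theta), r * r])
        # Unit gain at the resonance peak keeps amplitudes comparable.
        x = lfilter([1.0 - r], a, x)
    return x


def generate_glottal_waveform(spec: GlottalSpec, **meta) -> VoiceRecording:
    """Synthesize one phonation from a :class:`GlottalSpec`.

    Cycle onsets are spaced T_mean*(1+eps_i) apart with eps_i i.i.d.
    N(0, jitter_frac); cycle gains are 1+delta_i with delta_i i.i.d.
    N(0, shimmer_frac).  White noise is scaled so that the AC power of the
    harmonic part divided by the noise power equals 10^(hnr_db/10).
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    t_mean = 1.0 / spec.f0_hz
    n_samples = int(round(spec.duration_s * fs))
    width = 0.6 * t_mean  # pulse open-phase length, constant across cycles

    # Draw enough cycles to span the requested duration.
    n_draw = int(math.ceil(spec.duration_s / t_mean)) + 8
    eps = rng.normal(0.0, spec.jitter_frac, n_draw) if spec.jitter_frac > 0 else np.zeros(n_draw)
    if np.any(1.0 + eps <= 0.0):
        raise ValueError("jitter_frac so large that a cycle period became non-positive")
    delta = rng.normal(0.0, spec.shimmer_frac, n_draw) if spec.shimmer_frac > 0 else np.zeros(n_draw)
    if np.any(1.0 + delta <= 0.0):
        raise ValueError("shimmer_frac so large that a cycle amplitude became non-positive")
    periods = t_mean * (1.0 + eps)
    amps = 1.0 + delta
    onsets = np.concatenate(([0.0], np.cumsum(periods[:-1])))
    keep = onsets + width <= spec.duration_s
    periods, amps, onsets = periods[keep], amps[keep], onsets[keep]
    if periods.size < 2:
        raise ValueError("duration_s too short for two glottal cycles")

    x = np.zeros(n_samples)
    for onset, amp in zip(onsets, amps):
        i0 = int(math.ceil(onset * fs))
        i1 = min(int(math.floor((onset + width) * fs)), n_samples - 1)
        if i1 <= i0:
            continue
        phase = (np.arange(i0, i1 + 1) / fs - onset) / width
        x[i0:i1 + 1] += amp * 0.5 * (1.0 - np.cos(2.0 * math.pi * phase))

    if spec.formant_freqs_hz:
        x = _resonator_cascade(x, spec.formant_freqs_hz, fs)

    if math.isfinite(spec.hnr_db):
        harmonic_power = float(np.var(x))
        noise_std = math.sqrt(harmonic_power / (10.0 ** (spec.hnr_db / 10.0)))
        if noise_std <= 0.0 or not math.isfinite(noise_std):
            raise ValueError("target hnr_db unreachable for this signal")
        x = x + rng.normal(0.0, noise_std, n_samples)

    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x * (0.9 / peak)

    return VoiceRecording(
        samples=x,
        sample_rate_hz=fs,
        true_periods_s=periods,
        true_amplitudes=amps,
        true_hnr_db=spec.hnr_db,
        true_f0_hz=spec.f0_hz,
        **meta,
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class GroupEffects:
    """Per-group latent phonatory parameters (means and SDs)."""

    jitter_mean: float
    jitter_sd: float
    shimmer_mean: float
    shimmer_sd: float
    hnr_mean_db: float
    hnr_sd_db: float


@dataclass
class AgeDist:
    mean: float
    sd: float
    lo: float
    hi: float


def default_group_effects() -> dict[str, GroupEffects]:
    """Calibration of the three diagnostic groups.

    Chosen once to reproduce the qualitative group structure this pipeline
    assumes: bulbar-involved voices show clearly elevated jitter/shimmer and
    depressed HNR with the largest spread; ALS voices without bulbar signs
    sit in between with inflated variance; controls are tight and clean.
    """
    return {
        "C": GroupEffects(0.006, 0.0015, 0.030, 0.008, 22.0, 2.0),
        "B": GroupEffects(0.022, 0.0070, 0.095, 0.030, 12.0, 3.0),
        "NB": GroupEffects(0.012, 0.0060, 0.055, 0.025, 17.0, 4.0),
    }


def default_age_dists() -> dict[str, AgeDist]:
    # Control group ~12 years younger than the patient groups.
    return {
        "C": AgeDist(45.2, 12.2, 21.0, 68.0),
        "B": AgeDist(56.8, 12.3, 38.0, 84.0),
        "NB": AgeDist(58.3, 11.7, 37.0, 81.0),
    }


@dataclass
class CohortSpec:
    """Specification of a full labelled synthetic cohort."""

    n_control: int = 18
    n_bulbar: int = 14
    n_nonbulbar: int = 31
    vowels: tuple[str, ...] = VOWELS
    group_effects: dict[str, GroupEffects] = field(default_factory=default_group_effects)
    age_dists: dict[str, AgeDist] = field(default_factory=default_age_dists)
    # Fraction of males per group (study: 9/18, 3/14, 23/31).
    sex_ratio: dict[str, float] = field(
        default_factory=lambda: {"C": 0.5, "B": 3 / 14, "NB": 23 / 31}
    )
    # Linear aging injected into all groups alike, centered at 50 years so
    # the group_effects means stay interpretable at mid-cohort age.
    age_slopes: dict[str, float] = field(
        default_factory=lambda: {"jitter_frac": 5e-5, "shimmer_frac": 3e-4, "hnr_db": -0.05}
    )
    duration_s: float = 3.0
    sample_rate_hz: float = 44100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_bulbar, self.n_nonbulbar) < 0:
            raise ValueError("group counts must be >= 0")
        if self.n_control + self.n_bulbar + self.n_nonbulbar == 0:
            raise ValueError("empty cohort")
        for v in self.vowels:
            if v not in VOWELS:
                raise ValueError(f"unknown vowel label {v!r}")
        ge = self.group_effects
        if ge["B"].jitter_mean < ge["C"].jitter_mean or ge["B"].shimmer_mean < ge["C"].shimmer_mean:
            raise ValueError("group B jitter/shimmer means must be >= group C means")
        if ge["B"].hnr_mean_db > ge["C"].hnr_mean_db:
            raise ValueError("group B HNR mean must be <= group C mean")
        for dist in self.age_dists.values():
            if dist.lo <= 0:
                raise ValueError("ages must be positive")


_AGE_CENTER_YEARS = 50.0
_F0_BY_SEX = {"male": (120.0, 15.0, 80.0, 180.0), "female": (210.0, 25.0, 140.0, 280.0)}
# Utterance-to-utterance wobble of the subject latents (lognormal SD for the
# perturbation fractions, additive dB for HNR, multiplicative for F0).
_UTTER_LOG_SD = 0.15
_UTTER_HNR_SD = 0.8
_UTTER_F0_SD = 0.02


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def _draw_subjects(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counts = {"C": spec.n_control, "B": spec.n_bulbar, "NB": spec.n_nonbulbar}
    for group in GROUPS:
        n = counts[group]
        if n == 0:
            continue
        eff = spec.group_effects[group]
        ages = _truncated_normal(rng, spec.age_dists[group].mean, spec.age_dists[group].sd,
                                 spec.age_dists[group].lo, spec.age_dists[group].hi, n)
        n_male = int(round(spec.sex_ratio[group] * n))
        sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(sexes)
        jit = np.clip(rng.normal(eff.jitter_mean, eff.jitter_sd, n), 1e-4, 0.09)
        shm = np.clip(rng.normal(eff.shimmer_mean, eff.shimmer_sd, n), 1e-3, 0.09)
        hnr = np.clip(rng.normal(eff.hnr_mean_db, eff.hnr_sd_db, n), 3.0, 35.0)
        dage = ages - _AGE_CENTER_YEARS
        jit = np.clip(jit + spec.age_slopes["jitter_frac"] * dage, 1e-4, 0.09)
        shm = np.clip(shm + spec.age_slopes["shimmer_frac"] * dage, 1e-3, 0.09)
        hnr = np.clip(hnr + spec.age_slopes["hnr_db"] * dage, 3.0, 35.0)
        for i in range(n):
            mu, sd, lo, hi = _F0_BY_SEX[sexes[i]]
            f0 = float(_truncated_normal(rng, mu, sd, lo, hi, 1)[0])
            rows.append({
                "subject_id": f"{group}{i + 1:02d}",
                "group": group,
                "sex": sexes[i],
                "age": round(float(ages[i]), 1),
                "true_jitter_frac": jit[i],
                "true_shimmer_frac": shm[i],
                "true_hnr_db": hnr[i],
                "true_f0_hz": f0,
            })
    return pd.DataFrame(rows)


def _utterance_latents(row: pd.Series, rng: np.random.Generator) -> tuple[float, float, float, float]:
    jit = float(row.true_jitter_frac) * math.exp(rng.normal(0.0, _UTTER_LOG_SD))
    shm = float(row.true_shimmer_frac) * math.exp(rng.normal(0.0, _UTTER_LOG_SD))
    hnr = float(row.true_hnr_db) + rng.normal(0.0, _UTTER_HNR_SD)
    f0 = float(row.true_f0_hz) * (1.0 + rng.normal(0.0, _UTTER_F0_SD))
    return min(jit, 0.09), min(shm, 0.09), float(np.clip(hnr, 3.0, 35.0)), f0


def generate_cohort(spec: CohortSpec) -> tuple[list[VoiceRecording], pd.DataFrame]:
    """Generate one recording per (subject, vowel) plus the metadata table.

    Deterministic under ``spec.seed``.  Metadata carries subject id, group,
    sex and age; the ``true_*`` columns are the hidden per-subject latents.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    subjects = _draw_subjects(spec, rng)
    recordings: list[VoiceRecording] = []
    for _, row in subjects.iterrows():
        for vowel in spec.vowels:
            jit, shm, hnr, f0 = _utterance_latents(row, rng)
            gspec = GlottalSpec(
                f0_hz=f0,
                duration_s=spec.duration_s,
                sample_rate_hz=spec.sample_rate_hz,
                jitter_frac=jit,
                shimmer_frac=shm,
                hnr_db=hnr,
                formant_freqs_hz=VOWEL_FORMANTS[vowel],
                seed=int(rng.integers(2**31)),
            )
            recordings.append(generate_glottal_waveform(
                gspec,
                subject_id=str(row.subject_id),
                vowel=vowel,
                sex=str(row.sex),
                age_years=float(row.age),
                group=str(row.group),
            ))
    return recordings, subjects


def write_metadata(subjects: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write the cohort metadata CSV (ground-truth columns behind a flag)."""
    cols = ["subject_id", "group", "sex", "age"]
    if include_truth:
        cols += [c for c in subjects.columns if c.startswith("true_")]
    subjects[cols].to_csv(path, index=False)


def latent_feature_table(spec: CohortSpec, n_cycles: int = 300,
                         n_pitch_frames: int = 240,
                         independent_utterances: bool = False
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast features-only cohort: sample per-cycle period/amplitude tables
    from the generating distributions and run them through the actual
    perturbation formulas, bypassing waveform synthesis and analysis.

    Used for large statistical checks (aging correction at n=200, type-I
    error on null cohorts) where re-analyzing hundreds of waveforms would
    only add extraction noise, not information.

    ``independent_utterances=True`` redraws the voice latents for every
    utterance instead of holding them fixed per subject.  This removes
    speaker identity from the rows and makes them exchangeable — the
    correct null for type-I checks of the evaluation machinery, since a
    subject-structured cohort lets utterance-level folds score above
    chance by memorizing voices even when no group effect exists.
    """
    from .perturbation import PerturbationSettings, jitter_features, shimmer_features

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    subjects = _draw_subjects(spec, rng)
    settings = PerturbationSettings()
    rows = []
    for _, srow in subjects.iterrows():
        for vowel in spec.vowels:
            if independent_utterances:
                eff = spec.group_effects[str(srow.group)]
                fresh = srow.copy()
                fresh.true_jitter_frac = float(np.clip(
                    rng.normal(eff.jitter_mean, eff.jitter_sd), 1e-4, 0.09))
                fresh.true_shimmer_frac = float(np.clip(
                    rng.normal(eff.shimmer_mean, eff.shimmer_sd), 1e-3, 0.09))
                fresh.true_hnr_db = float(np.clip(
                    rng.normal(eff.hnr_mean_db, eff.hnr_sd_db), 3.0, 35.0))
                mu, sd, lo, hi = _F0_BY_SEX[str(srow.sex)]
                fresh.true_f0_hz = float(_truncated_normal(rng, mu, sd, lo, hi, 1)[0])
                jit, shm, hnr, f0 = _utterance_latents(fresh, rng)
            else:
                jit, shm, hnr, f0 = _utterance_latents(srow, rng)
            t_mean = 1.0 / f0
            periods = t_mean * (1.0 + rng.normal(0.0, jit, n_cycles))
            amps = np.clip(1.0 + rng.normal(0.0, shm, n_cycles), 1e-3, None)
            j = jitter_features(periods, settings)
            s = shimmer_features(periods, amps, settings)
            f0_track = f0 * (1.0 + rng.normal(0.0, 0.003, n_pitch_frames))
            rows.append({
                "subject_id": srow.subject_id,
                "vowel": vowel,
                "jitter_absolute_s": j.absolute_s,
                "jitter_relative_pct": j.relative_pct,
                "jitter_rap_pct": j.rap_pct,
                "jitter_ppq5_pct": j.ppq5_pct,
                "shimmer_relative_pct": s.relative_pct,
                "shimmer_db": s.db,
                "shimmer_apq3_pct": s.apq3_pct,
                "shimmer_apq5_pct": s.apq5_pct,
                "shimmer_apq11_pct": s.apq11_pct,
                "pitch_mean_hz": float(np.mean(f0_track)),
                "pitch_sd_hz": float(np.std(f0_track, ddof=1)),
                "pitch_min_hz": float(np.min(f0_track)),
                "pitch_max_hz": float(np.max(f0_track)),
                "hnr_mean_db": hnr + float(rng.normal(0.0, 0.5)),
                "hnr_sd_db": abs(float(rng.normal(0.5, 0.15))),
            })
    return pd.DataFrame(rows), subjects


def null_cohort_spec(seed: int = 0, **kwargs) -> CohortSpec:
    """Cohort with no group effect: every group draws voice latents from
    the control distribution, ages from the control age distribution, and
    sexes at the same 50/50 ratio (type-I checks).

    Demographics must be equalized along with the voice effects: the
    default sex ratios differ by group and F0 is sex-dependent, so a
    cohort that only equalized the voice latents would still carry a
    label-correlated pitch signal through its sex composition.
    """
    c_eff = default_group_effects()["C"]
    c_age = default_age_dists()["C"]
    return CohortSpec(
        group_effects={g: GroupEffects(**vars(c_eff)) for g in GROUPS},
        age_dists={g: AgeDist(**vars(c_age)) for g in GROUPS},
        sex_ratio={g: 0.5 for g in GROUPS},
        seed=seed,
        **kwargs,
    )
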