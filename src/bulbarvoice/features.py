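"""The 15 phonatory features of one sustained-vowel utterance.

Orchestrates trimming, pitch tracking, cycle extraction, the jitter and
shimmer families and frame-based HNR into a single feature vector:

jitter(absolute, relative, rap, ppq5), shimmer(relative, dB, apq3, apq5,
apq11), pitch(mean, SD, min, max), HNR(mean, SD).

"undefined" values (NaN) propagate from every stage and are never
silently replaced; the only imputation in the pipeline is the documented
shimmer(apq11) rule in :mod:`bulbarvoice.preprocess`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cycles import extract_cycles, trim_phonation
from .harmonicity import HarmonicitySettings, harmonicity
from .perturbation import (
    PerturbationSettings,
    jitter_features,
    shimmer_features,
)
from .pitch import PitchSettings, pitch_stats, track_pitch
from .recording import VoiceRecording, read_wav

logger = logging.getLogger(__name__)

#: Canonical column order of the feature table.
FEATURE_COLUMNS = [
    "jitter_absolute_s",
    "jitter_relative_pct",
    "jitter_rap_pct",
    "jitter_ppq5_pct",
    "shimmer_relative_pct",
    "shimmer_db",
    "shimmer_apq3_pct",
    "shimmer_apq5_pct",
    "shimmer_apq11_pct",
    "pitch_mean_hz",
    "pitch_sd_hz",
    "pitch_min_hz",
    "pitch_max_hz",
    "hnr_mean_db",
    "hnr_sd_db",
]

META_COLUMNS = ["subject_id", "vowel", "sex", "age_years", "group"]


@dataclass
class PhonatoryFeatures:
    jitter_absolute_s: float
    jitter_relative_pct: float
    jitter_rap_pct: float
    jitter_ppq5_pct: float
    shimmer_relative_pct: float
    shimmer_db: float
    shimmer_apq3_pct: float
    shimmer_apq5_pct: float
    shimmer_apq11_pct: float
    pitch_mean_hz: float
    pitch_sd_hz: float
    pitch_min_hz: float
    pitch_max_hz: float
    hnr_mean_db: float
    hnr_sd_db: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def extract_features(rec: VoiceRecording,
                     pitch_settings: PitchSettings | None = None,
                     perturbation_settings: PerturbationSettings | None = None,
                     harmonicity_settings: HarmonicitySettings | None = None,
                     energy_frac: float = 0.1) -> PhonatoryFeatures:
    """Full per-utterance analysis; pitch settings default by sex."""
    if pitch_settings is None:
        pitch_settings = PitchSettings.for_sex(rec.sex)
    if perturbation_settings is None:
        perturbation_settings = PerturbationSettings()
    if harmonicity_settings is None:
        harmonicity_settings = HarmonicitySettings()

    trimmed = trim_phonation(rec, energy_frac=energy_frac)
    track = track_pitch(trimmed, pitch_settings)
    pstats = pitch_stats(track)
    cyc = extract_cycles(trimmed, track)
    jit = jitter_features(cyc.periods_s, perturbation_settings)
    shm = shimmer_features(cyc.periods_s, cyc.peak_amplitudes, perturbation_settings)
    hnr = harmonicity(trimmed, harmonicity_settings)

    return PhonatoryFeatures(
        jitter_absolute_s=jit.absolute_s,
        jitter_relative_pct=jit.relative_pct,
        jitter_rap_pct=jit.rap_pct,
        jitter_ppq5_pct=jit.ppq5_pct,
        shimmer_relative_pct=shm.relative_pct,
        shimmer_db=shm.db,
        shimmer_apq3_pct=shm.apq3_pct,
        shimmer_apq5_pct=shm.apq5_pct,
        shimmer_apq11_pct=shm.apq11_pct,
        pitch_mean_hz=pstats.mean_hz,
        pitch_sd_hz=pstats.sd_hz,
        pitch_min_hz=pstats.min_hz,
        pitch_max_hz=pstats.max_hz,
        hnr_mean_db=hnr.mean_db,
        hnr_sd_db=hnr.sd_db,
    )


def extract_feature_table(recordings: Iterable[VoiceRecording], **kwargs) -> pd.DataFrame:
    """One feature row per utterance, with subject metadata columns."""
    rows = []
    for rec in recordings:
        feats = extract_features(rec, **kwargs)
        row = {
            "subject_id": rec.subject_id,
            "vowel": rec.vowel,
            "sex": rec.sex,
            "age_years": rec.age_years,
            "group": rec.group,
        }
        row.update(feats.to_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
    n_undef = int(df[FEATURE_COLUMNS].isna().sum().sum())
    if n_undef:
        logger.info("feature table contains %d undefined cells", n_undef)
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with canonical columns; "undefined" serialized as empty cells."""
    df.to_csv(path, index=False, na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def extract_from_directory(audio_dir: str | Path, metadata: pd.DataFrame,
                           **kwargs) -> pd.DataFrame:
    """Extract features for every ``<subject_id>_<vowel>.wav`` in a directory,
    joining sex/age/group from the metadata table."""
    audio_dir = Path(audio_dir)
    meta = metadata.set_index("subject_id")
    recordings = []
    for path in sorted(audio_dir.glob("*.wav")):
        stem = path.stem
        subject_id, _, vowel = stem.rpartition("_")
        if subject_id not in meta.index:
            raise ValueError(f"{path.name}: subject {subject_id!r} missing from metadata")
        row = meta.loc[subject_id]
        recordings.append(read_wav(
            path,
            subject_id=subject_id,
            vowel=vowel,
            sex=str(row["sex"]),
            age_years=float(row["age"]),
            group=str(row["group"]),
        ))
    return extract_feature_table(recordings, **kwargs)
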