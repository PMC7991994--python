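#!/usr/bin/env python
"""Simulate the default synthetic cohort and summarize its structure.

Generates the 63-subject cohort (18 controls, 14 ALS with bulbar
involvement, 31 without), five sustained vowels each, and writes the
subject metadata plus a per-group summary of the hidden voice latents to
results/.  Pass --write-audio to also dump the WAV files (large; goes to
scratch/ by default).

The summary shows what the downstream stages are asked to detect: the
bulbar group carries roughly 3-4x the control jitter/shimmer and ~10 dB
less HNR, the non-bulbar ALS group sits in between with inflated spread,
and controls are ~12 years younger, so the aging correction has real
work to do.
"""

import argparse
from pathlib import Path

from bulbarvoice.recording import write_wav
from bulbarvoice.synth import CohortSpec, generate_cohort, write_metadata

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--write-audio", action="store_true")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    spec = CohortSpec(seed=args.seed)
    recordings, subjects = generate_cohort(spec)
    args.out.mkdir(parents=True, exist_ok=True)
    write_metadata(subjects, args.out / "cohort_metadata.csv", include_truth=True)

    summary = subjects.groupby("group").agg(
        n=("subject_id", "size"),
        age_mean=("age", "mean"),
        jitter_mean=("true_jitter_frac", "mean"),
        shimmer_mean=("true_shimmer_frac", "mean"),
        hnr_mean_db=("true_hnr_db", "mean"),
    ).round(4)
    summary.to_csv(args.out / "cohort_group_summary.csv")
    print(f"{len(recordings)} recordings for {subjects.shape[0]} subjects (seed {args.seed})")
    print(summary.to_string())

    if args.write_audio:
        audio_dir = ROOT / "scratch" / "audio"
        audio_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_wav(audio_dir / f"{rec.subject_id}_{rec.vowel}.wav", rec)
        print(f"audio written to {audio_dir}")


if __name__ == "__main__":
    main()
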