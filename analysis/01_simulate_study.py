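#!/usr/bin/env python
"""Generate the synthetic 8-participant operating-room cleaning study.

Writes one folder per participant (joint-angle stream, subtask
annotations, load events) under ``scratch/study``.  Subtask intervals are
scaled to one fifth of their full-session durations so the whole analysis
chain runs in seconds; the study keeps all 17 subtask groups, the three
designed high-risk mover groups, and the 60 Hz sampling of the emulated
protocol.
"""

from pathlib import Path

from ergorula.synthetic import SessionConfig, generate_study, ground_truth

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"
SEED = 42

if __name__ == "__main__":
    config = SessionConfig(seed=SEED, n_participants=8, duration_scale=0.2)
    folders = generate_study(config, STUDY_DIR)
    print(f"wrote {len(folders)} participant sessions under {STUDY_DIR}")
    print("designed risk ordering (riskiest first):")
    for group in ground_truth(config)[:3]:
        print(f"  {group}")
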