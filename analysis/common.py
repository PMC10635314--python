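"""Shared plumbing for the numbered analysis scripts.

The reference synthetic trial (seed 1, default study conditions) lives
under ``scratch/synthetic_trial``; any script regenerates it on demand,
so scripts can be run independently and in any order. Result tables go
under ``results/``.
"""

from __future__ import annotations

from pathlib import Path

from clonodyn.simulate import GeneratorConfig, generate_trial, read_bundle, write_bundle

ROOT = Path(__file__).resolve().parent.parent
BUNDLE_DIR = ROOT / "scratch" / "synthetic_trial"
RESULTS_DIR = ROOT / "results"

TRIAL_SEED = 1


def ensure_bundle():
    """Generate (once) and load the reference synthetic trial bundle."""
    if not (BUNDLE_DIR / "manifest.yaml").exists():
        trial = generate_trial(GeneratorConfig(seed=TRIAL_SEED))
        write_bundle(trial, BUNDLE_DIR, force=True)
        print(f"generated reference trial bundle at {BUNDLE_DIR}")
    RESULTS_DIR.mkdir(exist_ok=True)
    return read_bundle(BUNDLE_DIR)
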