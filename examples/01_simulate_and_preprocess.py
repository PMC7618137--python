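"""Simulate a synthetic participant and run the preprocessing chain.

Generates retro-cue epochs with known ground truth, band-pass filters,
baseline-corrects, flags artifact trials, and prints the participant-level
screening statistics.
"""

from retrocue.preprocess import bandpass, baseline_correct, reject_artifacts, screen_participant
from retrocue.synth import SynthConfig, generate_epochs

cfg = SynthConfig(
    n_trials_per_condition=60,
    srate=250.0,
    rng_seed=1,
    artifact_frac_eeg=0.03,
    artifact_frac_heog=0.03,
)
epochs, truth = generate_epochs(cfg)
print(f"generated {epochs.n_trials} trials x {epochs.n_channels} channels "
      f"x {epochs.n_times} samples ({epochs.times[0]:g}..{epochs.times[-1]:g} ms)")

clean = reject_artifacts(baseline_correct(bandpass(epochs, 0.1, 40.0), (-200.0, 0.0)))
screen = screen_participant(clean)
n_flagged = int(clean.trial_table["reject_flag"].sum())
print(f"flagged {n_flagged} trials ({screen.reject_fraction:.1%}); "
      f"mean HEOG {screen.mean_heog_uv:+.2f} uV; keep participant: {screen.keep}")
# A participant is excluded above 40% rejection or beyond +-3.2 uV mean HEOG.
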