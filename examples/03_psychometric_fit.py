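"""Fitting cumulative-Gumbel psychometric curves to one synthetic session.

Generates a single subject's 378-trial tremor-bisection session, applies
the RT outlier rules, and extracts the bisection point (BP) and coefficient
of variation (CV) per tremor frequency.
"""

import numpy as np

from tremortime import psychometrics as psy, synthetic_data as sd

design = sd.DesignConfig(n_subjects=1, seed=42)
trials = sd.generate_dataset(
    design, sd.ObserverConfig(), modality="auditory", rng=np.random.default_rng(42)
)
print(f"session: {len(trials)} trials, {trials['duration_ms'].nunique()} durations")

kept, log = psy.filter_rts(trials)
row = log.iloc[0]
print(
    f"RT filter: {row['n_excluded_window']} outside 200-2000 ms, "
    f"{row['n_excluded_sd']} beyond 3 SD of log RT, {row['n_kept']} kept"
)

fits = psy.curves_by_condition(kept, collapse=("amplitude_N",))
print("\nper-frequency psychometric fits (pooled over amplitude):")
for _, f in fits.iterrows():
    print(
        f"  {int(f['frequency_Hz']):>2} Hz: BP = {f['bp_ms']:7.1f} ms, "
        f"CV = {f['cv']:.3f}  (n = {int(f['n'])})"
    )
# BP stays near the 2,000 ms geometric midpoint at every tremor frequency
# (accuracy spared) while CV grows with frequency (precision degraded) --
# the planted cue-combination effect.
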