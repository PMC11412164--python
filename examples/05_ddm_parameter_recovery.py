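"""Recovering Levy DDM parameters with quantile-probability fitting.

Simulates one condition from known parameters, refits it from the choice/RT
data alone, and prints true versus estimated values.
"""

from tremortime import ddm_fit
from tremortime.levy_ddm import DDMParams

true = DDMParams(v=1.5, a=1.6, z=0.5, t0=0.3, alpha=2.0)
report = ddm_fit.recovery_run(true, n_trials=5000, seed=1)

print(f"{'param':>6} {'true':>8} {'estimated':>10} {'rel err':>9}")
for k in ("v", "a", "z", "t0", "alpha"):
    rel = report.rel_error.get(k, 0.0)
    print(f"{k:>6} {report.true[k]:8.3f} {report.estimated[k]:10.3f} {rel:8.1%}")
# drift and threshold typically come back within a few percent at n = 5,000;
# the chi-square compares response proportions and RT quantiles between the
# data and model simulations replayed on a fixed noise bank
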