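"""Compare activation functions with the pooled one-sided t-test.

Uses the bundled published per-run accuracy tables (ten repetitions per
activation on the PolyU and CASIA multispectral palmprint databases) and
asks, for each pair, whether the first activation's mean accuracy is
significantly higher at alpha = 0.05.  H1 means "yes"; the t statistic
grows with the separation between the two run series.
"""

from hyperelm import two_sample_t_test
from hyperelm.reference_tables import load_activation_runs

runs = load_activation_runs()
for db in ("polyu", "casia"):
    print(f"{db}:")
    for better, worse in (("sigmoid", "sin"), ("sigmoid", "atan"), ("atan", "sin")):
        r = two_sample_t_test(runs[(db, better)], runs[(db, worse)])
        print(f"  {better:>7} > {worse:<5}?  t = {r.t:7.3f}  "
              f"p = {r.p:.3e}  -> {r.decision}")
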