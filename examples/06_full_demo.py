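"""End-to-end pipeline on synthetic data with a recovery report.

Equivalent to `triploase demo --out-dir demo_out --seed 1`; writes
per-stage TSVs plus summary.json and a run manifest.
"""

import json

from triploase.pipeline import run_demo

summary = run_demo("demo_out", seed=1, n_genes=300)
print(json.dumps(summary, indent=2, default=str))
# peg_sensitivity / cis_called_peg report imprinting-caller accuracy on the
# planted truth; factorial_ranking should read poe > ploidy > hybridity.
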