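"""Run the full naive + MAIC endpoint comparison on the synthetic trials.

The final stage: unadjusted comparisons of every efficacy and safety
endpoint, then the weighted (MAIC) comparisons using the weights from the
matching stage, each classified against the prespecified noninferiority
margins (13 pp response, 13 pp safety, HR 1.333 OS, HR 1.298 PFS).

Because the two synthetic trials share their outcome models (no true
regimen effect), the expected pattern is noninferiority nearly everywhere;
the MAIC rows shift the estimates toward the null relative to the naive
rows wherever the covariate shift had induced spurious differences.
"""

from pathlib import Path

from vtdmaic.comparative_stats import MarginSet
from vtdmaic.pipeline import render_report, run_maic, run_naive, write_outputs
from vtdmaic.synthetic_trials import (
    default_paperlike_config,
    profile_from_ipd,
    simulate_trial,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "comparison"

cfg_mod, cfg_label = default_paperlike_config()
mod = simulate_trial(cfg_mod)
label = simulate_trial(cfg_label)
profile = profile_from_ipd(mod)
margins = MarginSet()

naive = run_naive(mod, label, margins)
maic = run_maic(mod, label, profile, margins)
write_outputs(maic, OUT)

text, frame = render_report(naive + maic.results)
(OUT / "report_naive_and_maic.txt").write_text(text + "\n", encoding="utf-8")
print(text)
print(f"\nefficacy ESS {maic.weights['efficacy'].ess:.1f} of n={label.n}; "
      f"config hash {maic.config_hash}")
print(f"wrote results to {OUT}")
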