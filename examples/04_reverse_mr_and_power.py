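"""Reverse-direction MR and post-hoc power.

First checks the reverse direction — does the (null) disease causally
shift the taxa? — by swapping exposure and outcome roles with the relaxed
p < 1e-4 instrument threshold. Then evaluates the power of a
binary-outcome MR design: with 598 cases among 218,792 participants and
instruments explaining 2% of exposure variance, how detectable is an
OR of 1.7?
"""

from mrpipe import PipelineConfig, mr_power, no_reverse_signal, run_reverse
from mrpipe.simulate import SyntheticScenario, simulate_batch

base = SyntheticScenario(m_snps=60, m_causal=25, gamma_sd=0.15, seed=21)
batch = simulate_batch(base, n_taxa=5)  # all-null: no true effects either way

cfg = PipelineConfig(methods=("ivw",), run_presso=False, seed=4)
reverse = run_reverse(batch.outcome, batch.exposures, batch.ld, cfg)
for r in reverse:
    print(f"{r.exposure:45s} {r.classification}  ({r.reason or 'ok'})")
if no_reverse_signal(reverse):
    print("=> no significant reverse causal relationship\n")

n, cases = 218_792, 598
for r2 in (0.005, 0.01, 0.02, 0.05):
    p = mr_power(n_outcome=n, case_fraction=cases / n, r2_sum=r2, or_alt=1.7)
    flag = "adequate" if p >= 0.8 else "underpowered"
    print(f"instrument R2 = {r2:5.3f}:  power = {p:.2f}  ({flag})")
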