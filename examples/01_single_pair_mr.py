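"""Estimate a causal effect from one simulated exposure/outcome pair.

Simulates a microbiome-style exposure GWAS (18,340 individuals) and a rare
binary outcome GWAS (598 cases / 218,194 controls) with a true causal
effect theta = log 1.7, selects and harmonizes instruments, and prints
every estimator's odds ratio with its 95% CI. With a genuine effect all
five estimators should agree in direction; the IVW estimate is the primary
one and the rest are sensitivity analyses.
"""

import numpy as np

from mrpipe import PipelineConfig, SyntheticScenario, analyze_pair, simulate_pair

theta = float(np.log(1.7))
scenario = SyntheticScenario(m_snps=60, m_causal=25, gamma_sd=0.15,
                             theta=theta, seed=42)
pair = simulate_pair(scenario)

result = analyze_pair(pair.exposure, pair.outcome, pair.ld,
                      PipelineConfig(seed=7, n_boot=500, presso_n_sim=500))

print(f"instruments retained: {result.nsnp} (all F > 10)")
print(f"true causal OR: {np.exp(theta):.2f}")
print(f"{'method':<16}{'OR':>7}{'95% CI':>18}{'p':>12}")
for method, e in result.estimates.items():
    print(f"{method:<16}{e.or_:>7.2f}   [{e.or_low:5.2f}, {e.or_high:5.2f}]"
          f"{e.pvalue:>12.3g}")
s = result.sensitivity
print(f"\nCochran's Q = {s.q_stat:.2f} (p = {s.q_pvalue:.3f}) — "
      "no heterogeneity expected here")
print(f"Egger intercept = {s.egger_intercept:.4f} (p = {s.egger_intercept_p:.3f}) — "
      "near zero means no directional pleiotropy")
print(f"MR-PRESSO global p = {s.presso_global_p:.3f}, outliers: "
      f"{s.presso_outliers or 'none'}")
print(f"post-hoc power at the estimated OR: {result.power:.2f}")
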