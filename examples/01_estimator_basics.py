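"""Univariable MR estimators on a small hand-built instrument set.

Builds three aligned instruments, runs IVW, MR-Egger and the weighted
median, and prints the estimates as odds ratios per one-unit increase in
the exposure's log-odds liability.
"""

from mrkit import HarmonizedSet, cochran_q, ivw, mr_egger, to_odds_ratio, weighted_median

hs = HarmonizedSet.from_arrays(
    bx=[0.1, 0.2, 0.3],          # SNP effects on the exposure (log-odds)
    se_x=[0.01, 0.01, 0.01],
    by=[0.05, 0.08, 0.16],       # SNP effects on the outcome (log-odds)
    se_y=[0.01, 0.01, 0.02],
)

est = ivw(hs)
q, df, qp = cochran_q(hs, est)
slope, intercept = mr_egger(hs)
wm = weighted_median(hs, n_boot=1000, seed=1)

for name, e in [("IVW", est), ("Egger slope", slope), ("weighted median", wm)]:
    or_, lo, hi = to_odds_ratio(e)
    print(f"{name:16s} OR {or_:.3f} (95% CI {lo:.3f}-{hi:.3f})  p={e.pvalue:.3g}")
print(f"Egger intercept  {intercept.beta:+.4f}  p={intercept.pvalue:.3g}  "
      "(directional-pleiotropy test)")
print(f"Cochran's Q      {q:.2f} on {df} df, p={qp:.3g}  (heterogeneity)")

# The IVW weighted slope here is 330/725 ~ 0.455: each unit of log-odds
# liability raises the outcome's odds by ~58%. The Egger intercept near 0
# and the agreement between estimators indicate no directional pleiotropy.
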