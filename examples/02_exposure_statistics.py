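"""Time-weighted exposure statistics from per-frame scores.

Recreates the arithmetic of the reporting layer: the relative average risk
score over time (rel. av. RST) is the time-weighted mean score, and the
ergonomic risk potential (ERP) expresses it as a percentage of the
outcome's maximum possible score.
"""

from rulatime import erp, rel_av_rst, time_distribution
from rulatime.risk_stats import round_half_up

# 30% of frames at final score 4, 70% at final score 5
scores = [4] * 30 + [5] * 70
dist = time_distribution(scores, max_score=7)
rst = rel_av_rst(dist)
print("distribution:", {v: float(round(f, 3)) for v, f in sorted(dist.rel_time.items())})
print(f"rel. av. RST = 0.3 x 4 + 0.7 x 5 = {rst}")
print(f"ERP = {rst} / 7 x 100 = {round_half_up(erp(rst, 7), 2)} %")

# a cohort cell: a final-score rel. av. RST of 6.75 out of a maximum of 7
print(f"\nrel. av. RST 6.75 of max 7 -> ERP {round_half_up(erp(6.75, 7), 2)} %")
print("ERP close to 100% means nearly the whole task was spent at the")
print("worst possible score for that outcome.")
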