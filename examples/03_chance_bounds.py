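"""Chance-level upper confidence limits for BCI accuracy claims.

An observed accuracy only demonstrates real discrimination if it exceeds
the upper confidence limit of what guessing could achieve at the given
number of trials and significance level.
"""
from nirsbci import chance_upper_limit

for k, n in ((3, 288), (2, 144)):
    bound = chance_upper_limit(k, n, alpha=0.01)
    exact = chance_upper_limit(k, n, alpha=0.01, method="exact")
    print(f"{k}-class, n={n}: chance point {100 / k:.1f}%, "
          f"upper limit {bound:.1f}% (adjusted-Wald), {exact:.1f}% (exact binomial)")
# A three-class accuracy above ~40% on 288 segments, or a two-class
# accuracy above ~60% on 144, is significantly better than chance at the
# 99% confidence level.
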