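"""Reporting odds ratio straight from a 2x2 event-count table.

a/c = target-term events with the drug of interest / the comparator,
b/d = all other events with each.  Estimation is gated below 3 target
events per side; the CI is Woolf's log-normal interval.
"""

import math

from sedror import ContingencyTable, ror

t = ContingencyTable(a=9, b=9, c=21, d=86)
est = ror(t)
print(f"ROR = (a*d)/(b*c) = {est.ror:.3f}")
print(f"95% CI ({est.ci_low:.2f}, {est.ci_high:.2f})  p = {est.p_value:.4f}")
print(f"significant (CI excludes 1): {est.significant}")

# Woolf CIs are symmetric on the log scale: the geometric mean of the
# bounds recovers the point estimate.
print(f"sqrt(ci_low * ci_high) = {math.sqrt(est.ci_low * est.ci_high):.3f}")

# Reversing the comparison inverts the estimate exactly.
rev = ror(t.transposed())
print(f"reversed ROR = {rev.ror:.3f}; product = {est.ror * rev.ror:.6f}")

# Too few target events on either side -> gated, no estimate.
print(f"a=2 table gated: {ror(ContingencyTable(2, 50, 40, 500)).gated}")
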