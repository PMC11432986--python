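"""Descriptive summary of the bundled 364-report rhabdomyolysis case series.

The fixture reconstructs, deterministically, a published case series of
rhabdomyolysis reports for three sedatives; summarize() rebuilds the
demographic, seriousness and outcome tables with half-up 1-decimal
percentages.
"""

from sedror import fixture_from_tables, pct, summarize
from sedror.describe import cell
from sedror.selection import group_counts, primary_term_set

ds = fixture_from_tables()
counts = {g.value: n for g, n in group_counts(ds).items()}
total = sum(counts.values())
print(f"case reports: {total} across {len(counts)} exposure groups")
for g in ("DEX", "MID", "PRO", "MID/PRO"):
    print(f"  {g:8s} N={counts[g]:3d} ({pct(counts[g], total)}%)")

bundle = summarize(ds, primary_term_set())
for label, row in [
    ("male", "Sex: Male"),
    ("adults 18-64", "Age: 18-64 Years"),
    ("reported by HCPs", "Source: Healthcare Professional"),
]:
    n, p = cell(bundle.demographics, row, "Overall")
    print(f"{label}: N={n} ({p}%)")

n_fav, p_fav = cell(bundle.outcome_class, "Favourable", "Overall")
print(f"favourable outcome (recovered or recovering): N={n_fav} ({p_fav}%)")
# Each percentage uses the group's report count (demographics) or its
# target-event count (seriousness/outcome) as denominator.
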