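"""Cross-corpus comparisons on the published October-2009 GOA exponents.

The package ships the published per-species power-law exponents of the
October-2009 GOA corpora (the raw annotation files are an external
download). This script recomputes the three comparisons those numbers
support: the per-sub-ontology mean exponent, the paired test of
high-confidence (experimental evidence codes) vs low-confidence
(IEA-only) exponents, and the exponent-vs-corpus-size association.
"""

from gozipf import group_mean_beta, paired_t_test, size_exponent_association
from gozipf.datasets import goa_2009_exponent_records, goa_2009_hc_lc_pairs

records = goa_2009_exponent_records()
for aspect in ("BP", "MF", "CC"):
    print(f"mean beta, {aspect}: {group_mean_beta(records, aspect):.2f}")

pairs = goa_2009_hc_lc_pairs()
t, df, p_one = paired_t_test(pairs, sides="one")
_, _, p_two = paired_t_test(pairs, sides="two")
print(f"\nHC vs LC paired t-test over {len(pairs)} corpora: "
      f"t = {t:.2f}, df = {df}")
print(f"  one-sided p = {p_one:.3f}, two-sided p = {p_two:.3f}")

corr_distinct, corr_total, _ = size_exponent_association(records)
print(f"\npooled Spearman(beta, distinct terms) = {corr_distinct:.2f}")
print(f"pooled Spearman(beta, total annotations) = {corr_total:.2f}")
print("within each sub-ontology (5 corpora each):")
for aspect in ("BP", "MF", "CC"):
    sub = [r for r in records if r.aspect == aspect]
    cd, ct, _ = size_exponent_association(sub)
    print(f"  {aspect}: rho(distinct) = {cd:.2f}, rho(total) = {ct:.2f}")

# Expected output: BP annotations use a distinctly steeper exponent
# (~2.13) than MF (~1.81) and CC (~1.72); exponents from experimentally
# supported annotation exceed electronic-only ones (t ~ 3.3, p ~ 0.01
# one-sided). The pooled beta-vs-distinct-terms correlation (~0.8) is a
# sub-ontology confound — BP corpora are both richer and steeper; within
# a sub-ontology the five-point correlations (~0.5) are well within what
# chance produces, i.e. no clear size effect on the exponent.
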