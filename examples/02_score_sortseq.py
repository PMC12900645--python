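"""Simulate a sort-seq screen and compute mutational effect scores (MES).

Cells carrying each variant fluoresce lognormally around the variant's
true activity and are sorted into six log-spaced GFP gates; MES weights
each gate's pool-relative read enrichment by the gate's mean fluorescence.
"""

from scipy.stats import spearmanr

import ctnnbscan as cs
from ctnnbscan.simulate import SortSeqConfig, simulate_sortseq

result = simulate_sortseq(SortSeqConfig(seed=1))
table = cs.score(result.matrix)

ok = table["mes"].notna()
rho = spearmanr(table.loc[ok, "mes"], result.true_activity[ok]).statistic
print(f"scored variants        : {int(ok.sum())} / {len(table)}")
print(f"Spearman(MES, truth)   : {rho:.3f}")
print(f"low-confidence flagged : {int(table['low_confidence'].sum())} "
      "(underrepresented in the donor plasmid)")
print(f"strong calls (>18,000) : {(table['strength_call'] == 'strong').sum()}")
print()
print("strongest five variants by MES:")
print(table["mes"].nlargest(5).round(0).to_string())
print()
print("weakest five variants by MES:")
print(table["mes"].nsmallest(5).round(0).to_string())

# A high rank correlation with the generator's true activities shows the
# enrichment-weighting recovers the underlying fluorescence phenotype.
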