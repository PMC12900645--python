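"""Estimate a trinucleotide mutation spectrum and convert it to MLS values.

Mutational likelihood scores (MLS) give the background probability of each
amino-acid change, summing over all orderings of the required
single-nucleotide steps, each weighted by its trinucleotide-context
frequency.  A negative binomial likelihood-ratio test then asks whether
observed mutation counts simply track that background.
"""

import numpy as np

import ctnnbscan as cs
from ctnnbscan.mls import TrinucSpectrum, selection_test
from ctnnbscan.simulate import simulate_exome_snvs

# estimate a spectrum from 10,000 simulated exome SNVs
truth = TrinucSpectrum.random(np.random.default_rng(0))
snvs = simulate_exome_snvs(truth, 10_000, seed=1)
spectrum, rejected = cs.count_spectrum(snvs)
print(f"estimated 96-category spectrum from {spectrum.n_snvs} SNVs "
      f"({rejected} rejected)")

reference = cs.default_reference()
table = cs.hotspot_mls_table(reference, spectrum)
print(f"MLS table: {len(table)} amino-acid changes; "
      f"{(table['min_nt_changes'] == 1).sum()} reachable by one nucleotide change")
print()
print("highest-likelihood changes (most mutable given the spectrum):")
print(table.sort_values("mls", ascending=False).head(5)[["min_nt_changes", "mls"]])

# do observed counts track mutational likelihood? (null: yes -> large p)
single = table.loc[table["min_nt_changes"] == 1, "mls"].to_numpy()
rng = np.random.default_rng(4)
counts_null = rng.poisson(rng.gamma(1.0, 200.0, size=len(single)))
counts_sel = rng.poisson(rng.gamma(1.0, 200.0 * single / single.mean()))
print()
print(f"LRT p, counts independent of MLS : {selection_test(counts_null, single).p_value:.3f}")
print(f"LRT p, counts proportional to MLS: {selection_test(counts_sel, single).p_value:.2e}")

# A non-significant p for real tumor counts would mean mutation rates alone
# could explain the pattern; a significant slope means they cannot.
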