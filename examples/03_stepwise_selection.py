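"""Recover the active derived variables by stepwise selection.

Expression is generated with only H*exp(t) and W*log10(t+1) active (the
distance coefficient is zero).  Stepwise selection over all 18 candidate
products of {H, D, W} with functions of time should return exactly that
pair.
"""

from oct4expr import (CANDIDATE_TERMS, GenerativeConfig, generate_timecourse,
                      stepwise_select)

dataset = generate_timecourse(
    GenerativeConfig(n_genes=30, noise_sd=0.01,
                     true_beta=(0.5, 0.0, 1.2), seed=5))

selected = stepwise_select(dataset.records, criterion="pvalue")
print(f"candidates : {len(CANDIDATE_TERMS)} derived variables")
print(f"selected   : {sorted(selected)}")
print(f"truth      : ['H*exp(t)', 'W*log10(t+1)']")
# The multiplicity-adjusted p-value entry rule keeps inactive terms out
# even though several of them correlate strongly with the active pair.
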