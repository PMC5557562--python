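"""Encode peptide windows into the named feature vector.

A window of length L yields 10*L + 4 features: per position the five
Atchley factors, positional amino-acid frequency, predicted accessibility
and disorder, Kyte-Doolittle hydrophobicity and van der Waals volume;
plus four whole-peptide globals (average volume, GRAVY, net charge at
pH 7, isoelectric point).
"""

import metharg as m

proteins = m.generate_synthetic_dataset(m.SyntheticConfig(n_proteins=100, seed=42))
positives, negatives = m.build_window_sets(proteins, m.PipelineConfig())

table = m.fit_positional_frequency(positives)
vec = m.encode_window(positives[0], table)

print(f"window: {positives[0].peptide}")
print(f"features: {len(vec)} (= 10*19 + 4)")
for name in ["atchley_1_-1", "aafreq_-1", "hydro_0", "gravy", "net_charge", "pI"]:
    value = vec.values[vec.names.index(name)]
    print(f"  {name:14s} {value: .4f}")
# aafreq_-1 is high because glycine dominates position -1 in positives
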