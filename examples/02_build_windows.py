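"""Build the peptide-window training sets from annotated proteins.

Every arginine yields one 19-residue window (X-padded at the termini).
Pseudo-negatives are unlabeled windows below 40% identity to every
positive; both sets are then made internally non-redundant at the same
cut-off.
"""

import metharg as m

proteins = m.generate_synthetic_dataset(m.SyntheticConfig(n_proteins=100, seed=42))
config = m.PipelineConfig(window_length=19, identity_threshold=0.4)

positives, negatives = m.build_window_sets(proteins, config)
print(f"positive windows after filtering: {len(positives)}")
print(f"negative windows after filtering: {len(negatives)}")
w = positives[0]
print(f"example positive window: {w.peptide} ({w.protein_id}, R at {w.center_position})")
# the central residue is always R; windows near a terminus carry X padding
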