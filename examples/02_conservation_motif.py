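"""Profile per-column conservation and extract the signature motif.

Generates a 40-sequence family alignment with a conserved 13-column block
(columns 40-52) on a variable background, computes the entropy-based
conservation profile (weighted frequencies, window-3 smoothing,
z-normalization) and extracts the most conserved window containing the
configured β-hairpin columns.
"""

import numpy as np

from ghmotif import (
    MsaSpec,
    compute_profile,
    extract_motif,
    generate_msa,
    map_to_representative,
)

msa, truth = generate_msa(MsaSpec(seed=2))
profile = compute_profile(msa)
map_to_representative(profile, msa, start_number=100)

peak = int(np.nanargmax(profile.smoothed))
print(f"alignment: {msa.n_sequences} sequences x {msa.n_columns} columns")
print(f"planted conserved block: columns {truth.motif_start}-{truth.motif_end}")
print(f"smoothed conservation peak: column {peak}")

region = extract_motif(profile, hairpin_columns=(43, 49))
print(
    f"extracted motif: columns {region.column_start}-{region.column_end}, "
    f"representative residues {region.residue_start}-{region.residue_end}, "
    f"mean normalized conservation {region.mean_conservation:.2f}"
)
print("\nThe extracted window should coincide with the planted block: the")
print("conservation z-scores are positive across the block and negative")
print("outside it, so the maximal-sum window stops at the block edges.")
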