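"""Encode protein sequences under each of the six feature schemes.

Builds a tiny synthetic dataset, runs every encoder, and prints the
dimension and the first few descriptor values per scheme. The dimensions
(AAC 20, DPC 400, GPC 400, PseAAC 20+lambda, CTD 310, first-order ACF 531)
are fixed by the alphabet and the scheme definitions, not by the data.
"""

import numpy as np

from nifscan import (
    compute_aac,
    compute_acf,
    compute_ctd,
    compute_dpc,
    compute_gpc,
    compute_pseaac,
)
from nifscan.synthetic import random_sequences

seq = random_sequences(1, length_range=(120, 120), seed=0)[0]
print(f"sequence {seq.id}: length {seq.length}")
print(f"  {seq.residues[:60]}...")

for name, fv in [
    ("AAC", compute_aac(seq)),
    ("DPC", compute_dpc(seq)),
    ("GPC (gap 1)", compute_gpc(seq, gap=1)),
    ("PseAAC (lambda 1)", compute_pseaac(seq, lam=1)),
    ("CTD", compute_ctd(seq)),
    ("ACF (order 1)", compute_acf(seq, order=1)),
]:
    head = np.round(fv.values[:4], 4)
    print(f"{name:20s} dim {len(fv):4d}   first values {head}")

# Composition-style vectors are points on the simplex: they sum to one.
print("\nAAC sums to", compute_aac(seq).values.sum())
print("PseAAC sums to", compute_pseaac(seq, lam=1).values.sum())
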