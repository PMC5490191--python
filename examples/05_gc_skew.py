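"""Windowed GC-skew profile of a promoter-like sequence.

GC skew (G-C)/(G+C) on the non-template strand is a classical sequence
predictor of R-loop formation: skewed regions expose a C-rich template
that stabilizes the RNA:DNA hybrid.
"""

import numpy as np

from driptools import gc_skew_profile

rng = np.random.default_rng(4)
# unskewed background ... G-rich (skewed) CpG-island-like core ... background
background = "".join(rng.choice(list("ACGT"), size=600))
core = "".join(rng.choice(list("ACGT"), p=[0.2, 0.1, 0.5, 0.2], size=400))
seq = background + core + background

profile = gc_skew_profile(seq, window=100, step=50)
print(profile.round(3).to_string(index=False))
peak = profile.loc[profile["skew"].idxmax()]
print(f"\nmax skew {peak['skew']:.2f} in window [{int(peak['start'])}, {int(peak['end'])})")
print("the skewed core stands out from the ~0 background; in the genome such")
print("windows downstream of a TSS mark candidate R-loop-forming promoters")
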