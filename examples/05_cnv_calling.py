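"""Call CNVs from read depth against a within-family reference.

The reference is the per-target median of the healthy members' normalized
depths; proband log2 ratios near -1 indicate a heterozygous loss, near
+0.585 a single-copy gain.
"""

import pandas as pd

from twinseg.cnvcall import build_family_reference, log2_ratios, segment_and_call


def profile(depths):
    return pd.DataFrame({
        "chrom": "1",
        "start": [1_000_000 + i * 1000 for i in range(len(depths))],
        "end": [1_000_999 + i * 1000 for i in range(len(depths))],
        "depth": depths,
    })


healthy = [profile([100.0] * 100) for _ in range(3)]  # co-twin + parents
proband_depths = [100.0] * 100
for i in range(40, 50):
    proband_depths[i] = 50.0  # heterozygous deletion: half coverage

reference = build_family_reference(healthy)
ratios = log2_ratios(profile(proband_depths), reference)
segments = segment_and_call(ratios, subject="proband", min_targets=3)

for seg in segments:
    if seg.call != "neutral":
        print(
            f"{seg.call.upper()} {seg.chrom}:{seg.start}-{seg.end} "
            f"({seg.n_targets} targets, mean log2 ratio {seg.mean_log2_ratio:.3f})"
        )
# The mean log2 ratio near -1 matches a one-copy loss (log2(1/2) = -1).
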