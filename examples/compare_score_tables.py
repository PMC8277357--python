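"""Paired comparison of pre/post cognitive score tables.

Any subject x measure table works; here a toy battery of two measures. The
output mirrors the per-measure paired-t report: t, df, p and the standard
deviation of the paired differences.
"""

import pandas as pd

from nftrain import score_table_compare

pre = pd.DataFrame({
    "subject_id": ["s1", "s2", "s3", "s4", "s5"],
    "visual_memory_pct": [62.0, 71.0, 55.0, 68.0, 60.0],
    "median_latency_ms": [812.0, 745.0, 903.0, 799.0, 850.0],
})
post = pd.DataFrame({
    "subject_id": ["s1", "s2", "s3", "s4", "s5"],
    "visual_memory_pct": [70.0, 74.0, 61.0, 75.0, 66.0],
    "median_latency_ms": [798.0, 733.0, 871.0, 790.0, 841.0],
})

print(score_table_compare(pre, post).to_string(index=False))
print("\npositive mean_change: score rose post-training; "
      "for latencies lower is better.")
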