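"""Amplicon workflows: primer logic, breakpoint sentinels, homopolymers.

Classifies alleles from primer-pair amplification patterns, localizes a
fusion breakpoint from sentinel-site calls, and detects planted homopolymer
depth anomalies in a simulated 24-sample run.
"""

from paralocus import synthetic_data as sd
from paralocus.amplicon_tools import (
    AmpliconEvidence,
    SentinelCalls,
    classify_allele_from_primers,
    detect_homopolymer_variants,
    locate_cnl_breakpoint,
)

# 1. primer-pair classification
for amplified in [(True, False, False), (False, True, False), (True, False, True)]:
    ev = AmpliconEvidence("sample", amplified)
    print(amplified, "->", classify_allele_from_primers(ev))

# 2. sentinel-site breakpoint localization (NOCALL sites are skipped)
calls = SentinelCalls(
    ((1, "GENE"), (2, "GENE"), (3, "NOCALL"), (4, "PSEUDO"), (5, "PSEUDO"))
)
bi = locate_cnl_breakpoint(calls)
print(f"breakpoint between sentinel sites {bi.site_id_left} and {bi.site_id_right}")

# 3. homopolymer anomalies: a 0.5x cell (deletion) and a 1.5x cell (SNV)
matrix, truth = sd.simulate_run_depths(24, {(3, 0): 0.5, (7, 1): 1.5}, seed=5)
for flag in detect_homopolymer_variants(matrix):
    if flag.flag != "NONE":
        print(f"{flag.sample_id} pos {flag.position}: {flag.flag} (z={flag.z:.1f})")
print("truth:", truth)
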