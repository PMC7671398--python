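"""Harmonize exposure/outcome summary tables to a reference panel.

Shows the allele-orientation rules: matching alleles pass through, swapped
alleles flip the effect sign, mismatched and strand-ambiguous (A/T, C/G)
variants are dropped.
"""

import pandas as pd

from mrlink import harmonize
from mrlink.sumstats_io import SummaryStatsTable

cols = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "n"]
exposure = SummaryStatsTable.from_frame(pd.DataFrame([
    ("rs1", 1, 100, "A", "G", 0.10, 0.02, 50_000),   # matches panel
    ("rs2", 1, 200, "T", "C", 0.08, 0.02, 50_000),   # swapped vs panel
    ("rs3", 1, 300, "A", "T", 0.05, 0.02, 50_000),   # strand-ambiguous
    ("rs4", 1, 400, "A", "C", 0.07, 0.02, 50_000),   # alleles mismatch panel
], columns=cols))
outcome = SummaryStatsTable.from_frame(pd.DataFrame([
    ("rs1", 1, 100, "A", "G", 0.011, 0.01, 80_000),
    ("rs2", 1, 200, "C", "T", 0.009, 0.01, 80_000),
    ("rs3", 1, 300, "T", "A", 0.006, 0.01, 80_000),
    ("rs4", 1, 400, "G", "T", 0.004, 0.01, 80_000),
], columns=cols))
panel = pd.DataFrame({"snp": ["rs1", "rs2", "rs3", "rs4"],
                      "a1": ["A", "C", "A", "G"],
                      "a2": ["G", "T", "T", "T"]})

data = harmonize(exposure, outcome, panel)
print(data.to_frame()[["snp", "a1", "a2", "gamma_hat", "Gamma_hat"]])

# rs1 passes unchanged; rs2's exposure effect is sign-flipped onto the
# panel's C/T orientation; rs3 (A/T) and rs4 (unmatchable alleles) are gone.
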