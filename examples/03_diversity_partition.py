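"""POPGENE-style diversity per subspecies and the Shannon partition.

Dominant-allele frequencies come from band absence via q = sqrt(1 - f)
under HWE; per group the report averages Na, Ne, He and Shannon's I over
all band loci.  Pooling all plants gives the total diversity It; the mean
of the group values is the intra-group diversity Is, and S' = (It-Is)/It
is the share of diversity that lies between groups.
"""

import bandpop as bp

matrix, metadata, _ = bp.simulate_band_matrix(bp.SimulationConfig(seed=42))
report = bp.group_diversity(matrix, metadata.group_map("subspecies"))

print(report.per_group.round(3).to_string())
print(f"\nIt = {report.it_total:.3f}  Is = {report.is_within:.3f}  "
      f"Is/It = {report.is_over_it:.3f}  S' = {report.s_prime:.3f}")
# Is/It is the fraction of Shannon diversity held within subspecies;
# S' is the complementary between-subspecies fraction (they sum to 1).
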