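"""One-way AMOVA: how much band variation lies among vs within groups.

Squared Euclidean distances between 0/1 profiles (the number of
mismatching bands) are partitioned into among- and within-group variance
components; significance of the among-group component comes from
permuting the sample-to-group assignment.
"""

import bandpop as bp

matrix, metadata, _ = bp.simulate_band_matrix(bp.SimulationConfig(seed=42))
d2 = bp.squared_euclidean(matrix)

result = bp.amova_oneway(d2, metadata.group_map("subspecies"), n_perm=999, seed=42)
print(result.to_frame().round(4).to_string(index=False))
print(f"Phi_ST = {result.phi:.3f}")

# restrict to one subspecies and partition among its countries of origin
by_country = bp.amova_by_country(matrix, metadata, "hispanica", n_perm=999, seed=42)
print("\nhispanica, among countries:")
print(by_country.to_frame().round(4).to_string(index=False))
# The among-group percentage is Phi_ST; p is the +1-corrected fraction of
# permutations whose among-group component reaches the observed one.
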