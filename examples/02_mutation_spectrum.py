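"""Characterize the mutation spectrum of blood-restricted mutations.

Types each mutation (SNV / deletion / clustered multisite event), collapses
substitutions onto the pyrimidine strand, bins deletion lengths, and scores
junction microhomology - the radiation-exposure signature is an excess of
multi-nucleotide deletions and clustered events.
"""

import clonoscope as cs

fx = cs.make_reference_fixtures()
summary = cs.spectrum_summary(fx.table2_profiles, contexts=fx.table2_contexts)

print("events per animal:")
print(summary.per_animal)
print(f"\ntotals: {summary.total('DEL')} deletions, {summary.total('SNV')} SNVs, "
      f"{summary.total('MULTISITE')} multisite events")
print(f"deletion lengths (nt): {summary.deletion_length_hist}")
print(f"deletions with junction microhomology >= 2 nt: "
      f"{summary.microhomology_count} of {summary.n_deletions_with_context}")
print(f"substitution classes: {summary.substitution_hist}")
# Deletions outnumber substitutions and a fifth of long deletions show
# microhomology, consistent with end-joining repair of radiation damage.
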