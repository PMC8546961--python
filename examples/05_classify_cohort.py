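"""Classify a synthetic bacterial cohort by G6PDH cofactor specificity.

Generates 60 species with planted anchor residues (70% R, 20% H, 10% K),
isoform counts and glycolytic marker genes; maps each sequence's
beta2-alpha2 anchor by global alignment to the clean reference; calls
arginine carriers NADP-specific and everything else relaxed; and summarizes,
per taxonomic label, how isoform multiplicity and relaxed cofactor usage
co-vary with glycolytic strategy.
"""

from g6pdhkit import (AnchorReference, GenomeMarkers, ProteinRecord,
                      SynthSequenceSpec, build_species_profiles,
                      classify_records, gen_protein_set, summarize_taxon)

bundle = gen_protein_set(SynthSequenceSpec(
    n_species=60, substitution_rate=0.02, indel_rate=1 / 500, seed=42))
ref = AnchorReference(name="scaffold", sequence=bundle.reference,
                      anchor_pos=50)
records = [ProteinRecord(record_id=rid, sequence=seq,
                         species=row.species, taxon=row.taxon)
           for (rid, seq), row in zip(bundle.records,
                                      bundle.mapping.itertuples())]
calls, table = classify_records(records, ref)
print(table["call"].value_counts().to_string())
print()
markers = [GenomeMarkers(species=r.species, has_pfk=bool(r.pfk),
                         has_edd=bool(r.edd), has_eda=bool(r.eda))
           for r in bundle.markers.itertuples()]
profiles = build_species_profiles(records, calls, markers)
for summary in summarize_taxon(profiles):
    print(f"taxon {summary.taxon}: {summary.species_count} species")
    print(f"  isoform-count fractions: "
          + ", ".join(f"{b}: {f:.2f}" for b, f in summary.bin_fractions.items()))
    print(f"  glycolysis fractions:    "
          + ", ".join(f"{c}: {f:.2f}"
                      for c, f in summary.glycolysis_fractions.items()))
print()
correct = sum(c.residue == t for c, t in zip(calls,
                                             bundle.truth["anchor_residue"]))
print(f"anchor residues recovered: {correct}/{len(calls)}")
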