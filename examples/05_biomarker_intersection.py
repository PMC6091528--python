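"""Intersect two species' identified metabolites into a biomarker subset.

Uses the packaged fixture: 44 metabolites putatively identified from the
top-ranked bins of a two-species amphibian atrazine study, with per-species
presence and direction flags.  A biomarker is a metabolite perturbed in both
species; its per-species signs need not agree.
"""

import metabomark as mm

treefrog, toad = mm.load_cross_species_signs()
print(f"identified in the treefrog: {len(treefrog)} metabolites")
print(f"identified in the toad:     {len(toad)} metabolites")

biomarkers = mm.intersect_biomarkers(treefrog, toad)
print(f"\nshared biomarker subset: {len(biomarkers)} metabolites")
print(f"  concordant direction: {len(biomarkers.concordant())}")
print(f"  discordant direction: {len(biomarkers.discordant())}")
print("\ncompound              treefrog  toad")
for comp in biomarkers.compounds[:10]:
    a, b = biomarkers.signs[comp]
    print(f"{comp:<22}{a:^8}{b:^6}")
# 22 metabolites occur in both species; discordant rows (e.g. adenosine,
# + in one species and - in the other) are still biomarkers of exposure —
# the direction of the flux differs between species.
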