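"""Generate a synthetic ASV dataset with planted phenotype effects.

Builds the default study design (56 animals x 350 ASVs, three
phenotypes, 8 direct-effect ASVs per phenotype at |r| ~ 0.3 plus 6
mediated ASVs) and prints what was planted.
"""

from asvnet import SimulationConfig, generate

counts, taxonomy, phenotypes, truth = generate(SimulationConfig(seed=1))

print(f"counts: {len(counts.feature_ids)} ASVs x {len(counts.sample_ids)} samples")
print(f"zero fraction: {(counts.counts == 0).mean():.3f}")
print(f"phenotype means: {phenotypes.values.mean().round(2).to_dict()}")
for pheno, rows in truth.direct.items():
    signs = ["+" if b > 0 else "-" for _, b in rows]
    print(f"direct ASVs for {pheno}: {len(rows)} ({''.join(signs)})")
print(f"mediated ASVs: {len(truth.mediated)} (correlate with phenotypes "
      "only through their mediator)")
print(f"family over-represented among direct ASVs: {truth.enriched_family}")
# The planted structure is what the network analysis downstream should
# recover: direct ASVs as phenotype edges, mediated ones pruned by PCIT.
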