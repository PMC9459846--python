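"""Simulate a complete multi-omics study and write it to disk.

Generates 75 inbred lines under two water treatments with genotypes,
methylation, expression and four traits whose variance composition is
known exactly, then writes the four standard files.
"""

from pathlib import Path

from kernomics import write_matrix, write_phenotypes
from kernomics.simulate import make_paper_like_dataset

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

data = make_paper_like_dataset(seed=1, n_lines=75, n_snps=1000,
                               n_meth_sites=2000, n_genes=1500)

write_phenotypes(data["phenotypes"], out / "phenotypes.txt")
write_matrix(data["genotypes"], out / "genotypes.tsv")
write_matrix(data["methylation"], out / "methylation_levels.tsv")
write_matrix(data["expression"], out / "transcripts.tsv")

print(f"lines: {len(data['phenotypes'].lines)}")
print(f"traits: {data['phenotypes'].traits}")
for name in ("genotypes", "methylation", "expression"):
    print(f"{name}: {data[name].shape[0]} samples x {data[name].shape[1]} features")
for trait, truth in data["truths"].items():
    print(f"{trait}: true treatment effect {truth.treatment_effect:+.3f}, "
          f"true genomic PV2 {truth.pv2['snp']:.2f}")
# The treatment effects are the simulated shift (water-scarce minus
# control) on each trait's scale; the PV2 fractions are the exact share
# of phenotypic variance each generator component received.
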