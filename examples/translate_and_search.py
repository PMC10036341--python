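"""Find a precursor gene in nucleotide transcript models by homology.

Embeds a known precursor protein into a reverse-strand transcript model,
then retrieves it with a mutated (90% identical) query — the translated
homology search the discovery pipeline starts from.
"""

import random

from Bio.Seq import Seq

from npforge import SequenceRecord, SynthConfig, gen_precursors, search

rng = random.Random(5)
records, _ = gen_precursors(SynthConfig(seed=5, n_precursors=3))
precursor = records[0]

# one-codon-per-residue back-translation onto the reverse strand
codons = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
          "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
          "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
          "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
nt = "".join(codons[c] for c in precursor.sequence)
model = SequenceRecord("model_1", "AC" + str(Seq(nt).reverse_complement()) + "GTT")
decoy = SequenceRecord("model_2", "".join(rng.choice("ACGT") for _ in range(600)))

mutated = "".join(rng.choice("ACDEFGHILMNPQSTVWY") if rng.random() < 0.1 else c
                  for c in precursor.sequence)
query = SequenceRecord("query_precursor", mutated)

hits = search([query], [model, decoy], max_evalue=1e-5)
print(f"query: {query.id} ({len(mutated)} aa, ~90% identity to the truth)")
for h in hits:
    print(f"  hit {h.target_id} frame {h.frame:+d} score {h.score} "
          f"E={h.evalue:.2e} identity {h.identity_fraction:.2f}")
print("\nThe true model is recovered on the reverse strand (negative frame);"
      "\nthe random decoy scores below the E-value cutoff and is absent.")
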