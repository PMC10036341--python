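"""Annotate a neuropeptide precursor: signal, processing sites, peptides.

Generates one synthetic precursor and walks through the annotation the
pipeline applies to every candidate retrieved by homology search.
"""

from npforge import SynthConfig, annotate_precursor, gen_precursors

records, truths = gen_precursors(SynthConfig(seed=11, n_precursors=1))
record, truth = records[0], truths[0]

print(f"precursor {record.id} ({len(record)} aa)")
print(record.sequence)

ann = annotate_precursor(record)
sig = ann.signal
print(f"\nsignal peptide: residues 1..{sig.cleavage_after} "
      f"(hydrophobic core {sig.h_window[0]}..{sig.h_window[1]}, "
      f"score {sig.score:.2f}; generator truth: 1..{truth.signal_end})")

print("\nprocessing sites (maximal K/R runs):")
for site in ann.sites:
    print(f"  {site.motif} at {site.run_start}..{site.end_of_basic_run} "
          f"(tier {site.tier})")

print("\npredicted mature peptides:")
for pep in ann.peptides:
    amide = "-NH2 (Gly donor removed)" if pep.amidated else ""
    print(f"  {pep.start:>3}..{pep.end:<3} {pep.sequence}{amide}")

print("\nEach peptide is a fragment between processing sites; a trailing G"
      "\nbefore a site becomes a C-terminal amide on the mature peptide.")
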