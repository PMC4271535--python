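"""Published inputs of the Heliconius melpomene parent-offspring study.

These are the printed counts and scalar parameters of the original
experiment (two parents, 13 focal and 17 bait offspring), used to reproduce
its headline arithmetic without re-sequencing: the nine verified de novo
mutations with their base changes, the genome size, the spike-in tallies,
and the population-genetic scalars.
"""

STUDY_INPUTS = {
    "n_mutations": 9,
    "n_sites": 2.70e8,          # sites in the draft assembly scaffolds
    "n_focal": 13,
    "spike_total": 1000,
    "spike_callable": 456,
    "spike_called": 436,
    "pi": 0.024,                # 4-fold degenerate autosomal diversity
    "d": 0.14,                  # diversity-corrected neutral divergence to H. erato
    "generations_per_year": 4,
}

# wild-type -> mutant base of the nine verified de novo mutations
MELPOMENE_MUTATIONS = [
    ("A", "T"),
    ("T", "C"),
    ("G", "A"),
    ("A", "G"),
    ("G", "A"),
    ("T", "A"),
    ("G", "A"),
    ("G", "C"),
    ("T", "A"),
]
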