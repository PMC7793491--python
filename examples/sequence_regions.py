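"""Parse i-motif repeat notation and inspect regions and C:C+ pairing.

An intramolecular i-motif has four cytosine tracts (the core) joined by
three loops; the tracts pair up (1 with 3, 2 with 4) through
hemi-protonated C:C+ base pairs.
"""

from tspc4 import assign_regions, build_cc_pair_topology, parse_imotif_notation

seq = parse_imotif_notation("d[(CCCTAA)3CCC]", name="CCCTA2")
print(f"{seq.name}: {seq.sequence}  ({seq.n_residues} nt)")
print(f"tracts (1-based spans): {seq.tracts}")
print(f"loops:  {seq.loops}  sequences {seq.loop_sequences()}")

regions = assign_regions(seq)
print(f"core residues: {regions.residues('core')}")

for register in ("aligned", "shifted"):
    topology = build_cc_pair_topology(seq, register=register)
    print(f"{register} register C:C+ pairs: {', '.join(topology.names())}")

# The tract/loop spans tile the sequence; each register yields
# 2 x tract-length pairs between partner tracts 1-3 and 2-4.
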