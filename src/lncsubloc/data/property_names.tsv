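index	column	description
p1	twist	helical twist angle between successive base pairs (degrees)
p2	tilt	tilt angle of the base-pair step (degrees)
p3	roll	roll angle of the base-pair step (degrees)
p4	shift	shift displacement of the base-pair step (angstrom)
p5	slide	slide displacement of the base-pair step (angstrom)
p6	rise	rise between successive base pairs (angstrom)
p7	enthalpy	nearest-neighbour duplex formation enthalpy (kcal/mol)
p8	entropy	nearest-neighbour duplex formation entropy (cal/mol/K)
p9	free_energy	nearest-neighbour duplex free energy at 37 C (kcal/mol)
p10	gc_content	fraction of G or C residues in the k-mer
p11	purine_content	fraction of A or G residues in the k-mer
p12	keto_content	fraction of G or T residues in the k-mer
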