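subject_semtype	predicate	object_semtype
Pharmacologic Substance	causes	Disease or Syndrome
Pharmacologic Substance	causes	Cell Function
Pharmacologic Substance	treats	Disease or Syndrome
Pharmacologic Substance	prevents	Disease or Syndrome
Pharmacologic Substance	inhibits	Gene or Genome
Pharmacologic Substance	stimulates	Gene or Genome
Pharmacologic Substance	interacts_with	Pharmacologic Substance
Pharmacologic Substance	administered_to	Population Group
Amino Acid, Peptide, or Protein	causes	Disease or Syndrome
Amino Acid, Peptide, or Protein	interacts_with	Pharmacologic Substance
Amino Acid, Peptide, or Protein	stimulates	Cell Function
Gene or Genome	associated_with	Disease or Syndrome
Gene or Genome	predisposes	Disease or Syndrome
Disease or Syndrome	process_of	Population Group
Disease or Syndrome	coexists_with	Disease or Syndrome
Disease or Syndrome	isa	Disease or Syndrome
Body Part, Organ, or Organ Component	location_of	Disease or Syndrome
Disease or Syndrome	part_of	Body Part, Organ, or Organ Component
Diagnostic Procedure	diagnoses	Disease or Syndrome
Therapeutic or Preventive Procedure	treats	Disease or Syndrome
Therapeutic or Preventive Procedure	uses	Pharmacologic Substance
Bacterium	causes	Disease or Syndrome
Virus	causes	Disease or Syndrome
Pathologic Function	affects	Cell Function
Neoplastic Process	produces	Amino Acid, Peptide, or Protein
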