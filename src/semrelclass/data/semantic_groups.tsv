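semantic_type	semantic_group
Amino Acid, Peptide, or Protein	Chemicals and Drugs
Antibiotic	Chemicals and Drugs
Bacterium	Living Beings
Biologic Function	Physiology
Body Part, Organ, or Organ Component	Anatomy
Cell	Anatomy
Cell Function	Physiology
Clinical Drug	Chemicals and Drugs
Diagnostic Procedure	Procedures
Disease or Syndrome	Disorders
Enzyme	Chemicals and Drugs
Finding	Disorders
Gene or Genome	Genes and Molecular Sequences
Laboratory Procedure	Procedures
Lipid	Chemicals and Drugs
Mental or Behavioral Dysfunction	Disorders
Neoplastic Process	Disorders
Organic Chemical	Chemicals and Drugs
Organism Function	Physiology
Pathologic Function	Disorders
Pharmacologic Substance	Chemicals and Drugs
Population Group	Living Beings
Sign or Symptom	Disorders
Therapeutic or Preventive Procedure	Procedures
Tissue	Anatomy
Virus	Living Beings
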