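{
 "version": "1",
 "pathogenic_organisms": [
  "escherichia coli",
  "klebsiella pneumoniae",
  "klebsiella oxytoca",
  "proteus mirabilis",
  "enterobacter cloacae",
  "citrobacter freundii",
  "citrobacter koseri",
  "pseudomonas aeruginosa",
  "enterococcus faecalis",
  "enterococcus faecium",
  "staphylococcus saprophyticus",
  "serratia marcescens",
  "streptococcus agalactiae"
 ],
 "uti_explicit_dx": [
  "urinary tract infection",
  "uti",
  "cystitis",
  "acute cystitis",
  "pyelonephritis",
  "acute pyelonephritis",
  "urinary tract infection, site not specified"
 ],
 "uti_relevant_antibiotics": [
  "nitrofurantoin",
  "trimethoprim-sulfamethoxazole",
  "cephalexin",
  "ciprofloxacin",
  "levofloxacin",
  "fosfomycin",
  "amoxicillin-clavulanate",
  "ceftriaxone"
 ],
 "nonspecific_uti_attributable_dx": [
  "dysuria",
  "urinary frequency",
  "hematuria",
  "abdominal pain",
  "flank pain",
  "altered mental status",
  "fever, unspecified"
 ],
 "alternative_infectious_dx": [
  "pneumonia",
  "cellulitis",
  "otitis media",
  "pharyngitis",
  "sexually transmitted infection",
  "intra-abdominal infection"
 ]
}
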