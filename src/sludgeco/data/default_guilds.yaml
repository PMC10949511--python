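# Default functional-guild definitions for activated-sludge communities.
# Each guild is a list of {rank, label} patterns matched case-insensitively
# against the Silva-style lineage; "Candidatus " prefixes are normalized.
# Replace with a study-specific table if one is available.
AOB:
  - {rank: family, label: Nitrosomonadaceae}
  - {rank: genus, label: Nitrosomonas}
  - {rank: genus, label: oc32}
  - {rank: genus, label: Ellin6067}
  - {rank: genus, label: DSSD61}
  - {rank: genus, label: mle1-7}
  - {rank: genus, label: 966-1}
  - {rank: genus, label: Nitrosococcus}
  - {rank: genus, label: Nitrosospira}
NOB:
  - {rank: genus, label: Nitrospira}
  - {rank: genus, label: Nitrobacter}
  - {rank: genus, label: Nitrotoga}
  - {rank: genus, label: Candidatus Nitrotoga}
  - {rank: genus, label: Nitrolancea}
  - {rank: genus, label: Nitrococcus}
  - {rank: genus, label: Nitrospina}
  - {rank: class, label: P9X2b3D02}
PAO:
  - {rank: genus, label: Candidatus Accumulibacter}
  - {rank: genus, label: Tetrasphaera}
BFB:
  - {rank: genus, label: Acinetobacter}
  - {rank: genus, label: Caldilinea}
  - {rank: genus, label: Gordonia}
  - {rank: genus, label: Moraxella}
  - {rank: genus, label: Mycobacterium}
  - {rank: genus, label: Skermania}
  - {rank: genus, label: Thiothrix}
  - {rank: genus, label: Defluviicoccus}
  - {rank: genus, label: Candidatus Microthrix}
anammox:
  - {rank: genus, label: Candidatus Brocadia}
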