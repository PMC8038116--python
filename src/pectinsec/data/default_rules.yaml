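# Default linkage -> domain assignment rules for spruce-bark pectic fractions
# (Pettolino-style diagnostic linkages).  Rules are data so they can be
# adapted to other tissues.
#
# Assignment order: GalA backbone split, direct claims, terminal demands
# (in listed order, sources drawn in priority order), terminal remainders,
# then everything left goes to the fallback domain.

gala_split: true

direct:
  Arabinan: ["3-Araf", "5-Araf", "3,5-Araf", "2,5-Araf", "2,3,5-Araf"]
  AG-I: ["4-Galp", "4,6-Galp", "3,4-Galp"]
  AG-II: ["3-Galp", "6-Galp", "3,6-Galp", "2-Araf"]
  RG-I: ["2-Rhap", "2,4-Rhap"]
  HG: ["t-GalpA"]
  HX: ["4-Xylp"]
  HM: ["4-Manp", "4,6-Manp", "4-Glcp", "4,6-Glcp"]

terminal_demands:
  # AG-I galactan branch points (4,6- and 3,4-Galp) carry arabinose, then
  # galactose, terminals.
  - domain: AG-I
    demand: ["4,6-Galp", "3,4-Galp"]
    sources: ["t-Araf", "t-Galp"]
  # AG-II 3,6-Galp branch points carry rhamnose, arabinopyranose or
  # galactose terminals, in that order.
  - domain: AG-II
    demand: ["3,6-Galp"]
    sources: ["t-Rhap", "t-Arap", "t-Galp"]

terminal_remainders:
  # Terminal arabinofuranose not consumed by arabinogalactan branch points
  # caps the arabinan side chains.
  t-Araf: Arabinan

fallback: Others
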