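{
  "metanode_kinds": [
    "Anatomy",
    "Biological Process",
    "Cellular Component",
    "Compound",
    "Disease",
    "Gene",
    "Molecular Function",
    "Pathway",
    "Pharmacologic Class",
    "Side Effect",
    "Symptom"
  ],
  "metaedge_tuples": [
    ["Anatomy", "Gene", "downregulates", "both"],
    ["Anatomy", "Gene", "expresses", "both"],
    ["Anatomy", "Gene", "upregulates", "both"],
    ["Compound", "Compound", "resembles", "both"],
    ["Compound", "Disease", "palliates", "both"],
    ["Compound", "Disease", "treats", "both"],
    ["Compound", "Gene", "binds", "both"],
    ["Compound", "Gene", "downregulates", "both"],
    ["Compound", "Gene", "upregulates", "both"],
    ["Compound", "Side Effect", "causes", "both"],
    ["Disease", "Anatomy", "localizes", "both"],
    ["Disease", "Disease", "resembles", "both"],
    ["Disease", "Gene", "associates", "both"],
    ["Disease", "Gene", "downregulates", "both"],
    ["Disease", "Gene", "upregulates", "both"],
    ["Disease", "Symptom", "presents", "both"],
    ["Gene", "Biological Process", "participates", "both"],
    ["Gene", "Cellular Component", "participates", "both"],
    ["Gene", "Gene", "covaries", "both"],
    ["Gene", "Gene", "interacts", "both"],
    ["Gene", "Gene", "regulates", "forward"],
    ["Gene", "Molecular Function", "participates", "both"],
    ["Gene", "Pathway", "participates", "both"],
    ["Pharmacologic Class", "Compound", "includes", "both"]
  ],
  "kind_to_abbrev": {
    "Anatomy": "A",
    "Biological Process": "BP",
    "Cellular Component": "CC",
    "Compound": "C",
    "Disease": "D",
    "Gene": "G",
    "Molecular Function": "MF",
    "Pathway": "PW",
    "Pharmacologic Class": "PC",
    "Side Effect": "SE",
    "Symptom": "S",
    "associates": "a",
    "binds": "b",
    "causes": "c",
    "covaries": "c",
    "downregulates": "d",
    "expresses": "e",
    "includes": "i",
    "interacts": "i",
    "localizes": "l",
    "palliates": "p",
    "participates": "p",
    "presents": "p",
    "regulates": "r",
    "resembles": "r",
    "treats": "t",
    "upregulates": "u"
  }
}
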