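# Default semantic-network schema: 10 node classes linked by 12 edge types.
# Node classes cover the entity kinds of a systems chemical-biology network
# (drugs/compounds, protein targets, genes and the annotation vocabularies
# that make two compounds or two targets comparable). Edit freely; loaders
# validate every graph against whichever schema is supplied.
node_classes:
  - Compound
  - Target
  - Gene
  - GOTerm
  - Pathway
  - Substructure
  - ChemicalOntology
  - SideEffect
  - Tissue
  - Disease

# edge type -> the (unordered) pair of node classes it may connect.
# A single repeated class (e.g. PPI) means both endpoints share that class.
edge_types:
  bind: [Compound, Target]
  express: [Compound, Target]
  hasSubstructure: [Compound, Substructure]
  hasChemicalOntology: [Compound, ChemicalOntology]
  hasSideEffect: [Compound, SideEffect]
  treat: [Compound, Disease]
  hasGO: [Target, GOTerm]
  hasPathway: [Target, Pathway]
  hasTissue: [Target, Tissue]
  PPI: [Target, Target]
  encode: [Gene, Target]
  causeDisease: [Gene, Disease]
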