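# Constituent ortholog data sources and the datasets each contributes.
# Some projects ship several ortholog categories; each category is one
# constituent algorithm (one signature bit).  13 sources -> 17 datasets.
sources:
  - name: EggNOG
    category: graph-based
    datasets: [EggNOG-COGs, EggNOG-KOGs, EggNOG-NOGs]
  - name: Ensembl
    category: tree-based
    datasets: [Ensembl Compara]
  - name: Hieranoid
    category: hybrid tree- and graph-based
    datasets: [Hieranoid]
  - name: Homologene
    category: hybrid tree- and graph-based
    datasets: [Homologene]
  - name: InParanoid
    category: graph-based
    datasets: [InParanoid]
  - name: Isobase
    category: PPI network-based
    datasets: [Isobase]
  - name: MetaPhOrs
    category: tree-based
    datasets: [MetaPhOrs]
  - name: OMA
    category: graph-based
    datasets: [OMA]
  - name: OrthoDB
    category: tree-based
    datasets: [OrthoDB]
  - name: OrthoMCL
    category: graph-based
    datasets: [OrthoMCL]
  - name: PANTHER
    category: tree-based
    datasets: [PANTHER]
  - name: RoundUp
    category: graph-based
    datasets: [Roundup]
  - name: TreeFam
    category: tree-based
    datasets: [TreeFam]
  - name: IsoRank
    category: PPI and GI network-based
    datasets: [IsoRankN-PPI, IsoRankN2-GI]
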