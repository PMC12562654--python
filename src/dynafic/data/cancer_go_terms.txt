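# Cancer-hallmark GO term list shipped as the default cancer-relevance set
# for the CGES metric.  One Gene Ontology identifier per line; keyword-matched
# against hallmark processes (proliferation, apoptosis evasion, angiogenesis,
# invasion/metastasis, genome instability, tumor-promoting inflammation,
# energy metabolism, immune evasion, replicative immortality, growth signaling).
# Replace with a curated list for a production analysis.
GO:0008283  # cell population proliferation
GO:0042127  # regulation of cell population proliferation
GO:0008284  # positive regulation of cell population proliferation
GO:0008285  # negative regulation of cell population proliferation
GO:0007049  # cell cycle
GO:0051726  # regulation of cell cycle
GO:0000082  # G1/S transition of mitotic cell cycle
GO:0000086  # G2/M transition of mitotic cell cycle
GO:0007346  # regulation of mitotic cell cycle
GO:0045787  # positive regulation of cell cycle
GO:0045786  # negative regulation of cell cycle
GO:0006915  # apoptotic process
GO:0042981  # regulation of apoptotic process
GO:0043065  # positive regulation of apoptotic process
GO:0043066  # negative regulation of apoptotic process
GO:0097190  # apoptotic signaling pathway
GO:2001233  # regulation of apoptotic signaling pathway
GO:0008219  # cell death
GO:0010941  # regulation of cell death
GO:0012501  # programmed cell death
GO:0001525  # angiogenesis
GO:0045765  # regulation of angiogenesis
GO:0045766  # positive regulation of angiogenesis
GO:0001837  # epithelial to mesenchymal transition
GO:0010717  # regulation of epithelial to mesenchymal transition
GO:0016477  # cell migration
GO:0030334  # regulation of cell migration
GO:0030335  # positive regulation of cell migration
GO:0016337  # single organismal cell-cell adhesion
GO:0007155  # cell adhesion
GO:0030155  # regulation of cell adhesion
GO:0033627  # cell adhesion mediated by integrin
GO:0006281  # DNA repair
GO:0006974  # DNA damage response
GO:0000724  # double-strand break repair via homologous recombination
GO:0006298  # mismatch repair
GO:0031570  # DNA integrity checkpoint signaling
GO:0000077  # DNA damage checkpoint signaling
GO:0007569  # cell aging
GO:0090398  # cellular senescence
GO:2000772  # regulation of cellular senescence
GO:0032200  # telomere organization
GO:0000723  # telomere maintenance
GO:0006954  # inflammatory response
GO:0050727  # regulation of inflammatory response
GO:0002367  # cytokine production involved in immune response
GO:0001816  # cytokine production
GO:0002682  # regulation of immune system process
GO:0002837  # regulation of immune response to tumor cell
GO:0002418  # immune response to tumor cell
GO:0006096  # glycolytic process
GO:0006006  # glucose metabolic process
GO:0061621  # canonical glycolysis
GO:0046323  # glucose import
GO:0001666  # response to hypoxia
GO:0071456  # cellular response to hypoxia
GO:0097411  # hypoxia-inducible factor-1alpha signaling pathway
GO:0016055  # Wnt signaling pathway
GO:0030111  # regulation of Wnt signaling pathway
GO:0060070  # canonical Wnt signaling pathway
GO:0007169  # transmembrane receptor protein tyrosine kinase signaling pathway
GO:0000165  # MAPK cascade
GO:0043408  # regulation of MAPK cascade
GO:0014065  # phosphatidylinositol 3-kinase signaling
GO:0043491  # protein kinase B signaling
GO:0031929  # TOR signaling
GO:0007179  # transforming growth factor beta receptor signaling pathway
GO:0038202  # TORC1 signaling
GO:0072331  # signal transduction by p53 class mediator
GO:0030330  # DNA damage response, signal transduction by p53 class mediator
GO:0007219  # Notch signaling pathway
GO:0008543  # fibroblast growth factor receptor signaling pathway
GO:0048015  # phosphatidylinositol-mediated signaling
GO:0035329  # hippo signaling
GO:0070848  # response to growth factor
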