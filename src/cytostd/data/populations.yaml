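# Default synthetic PBMC panel.
#
# Ten channels: forward/side scatter, four surface markers, four
# intracellular cytokines.  Populations are Gaussian components on a
# log10 latent scale (channel value = 10^latent), so `mean` entries are
# decades and `sigma` entries are decades of spread.  These defaults are
# tuning for the example pipeline, not measured biology: the marker
# logic is the qualitative one used in PBMC immunophenotyping
# (monocytes CD14-high, pDC CD123-high, mDC CD11c-high, B cells
# MHC-II-high/CD14-low, debris low-scatter), with two deliberately
# unannotated "novel" populations for the clustering stage to find.
#
# `responders` makes cytokine channels bimodal inside the
# antigen-presenting populations, emulating a stimulated sample:
# `fraction` of the population's events get the listed cytokine means
# instead of the baseline ones.

channels: [FSC-A, SSC-A, CD123, CD11c, MHC-II, CD14, IL-6, IL-12, TNF-a, IFN-a]
fluorescence_channels: [CD123, CD11c, MHC-II, CD14, IL-6, IL-12, TNF-a, IFN-a]
range: 262144
scatter_sigma: 0.06
marker_sigma: 0.15

populations:
  monocytes:
    weight: 0.28
    mean: {FSC-A: 5.10, SSC-A: 4.95, CD123: 1.5, CD11c: 2.9, MHC-II: 3.0,
           CD14: 3.7, IL-6: 1.5, IL-12: 1.4, TNF-a: 1.5, IFN-a: 1.3}
    responders:
      fraction: 0.40
      mean: {IL-6: 3.4, IL-12: 3.1, TNF-a: 3.5}
  mDC:
    weight: 0.10
    mean: {FSC-A: 4.95, SSC-A: 4.65, CD123: 1.5, CD11c: 3.6, MHC-II: 3.6,
           CD14: 1.8, IL-6: 1.5, IL-12: 1.5, TNF-a: 1.4, IFN-a: 1.3}
    responders:
      fraction: 0.35
      mean: {IL-12: 3.3, TNF-a: 3.2}
  pDC:
    weight: 0.07
    mean: {FSC-A: 4.90, SSC-A: 4.55, CD123: 3.6, CD11c: 1.5, MHC-II: 2.6,
           CD14: 1.6, IL-6: 1.4, IL-12: 1.4, TNF-a: 1.4, IFN-a: 1.4}
    responders:
      fraction: 0.45
      mean: {IFN-a: 3.5, TNF-a: 2.9}
  B cells:
    weight: 0.25
    mean: {FSC-A: 4.85, SSC-A: 4.50, CD123: 1.4, CD11c: 1.5, MHC-II: 3.7,
           CD14: 1.5, IL-6: 1.4, IL-12: 1.3, TNF-a: 1.4, IFN-a: 1.3}
  debris/dead:
    weight: 0.15
    mean: {FSC-A: 4.20, SSC-A: 4.20, CD123: 1.2, CD11c: 1.2, MHC-II: 1.5,
           CD14: 1.3, IL-6: 1.3, IL-12: 1.2, TNF-a: 1.3, IFN-a: 1.2}
  novel-1:
    weight: 0.08
    mean: {FSC-A: 5.00, SSC-A: 4.80, CD123: 2.6, CD11c: 2.6, MHC-II: 2.4,
           CD14: 1.6, IL-6: 1.5, IL-12: 1.4, TNF-a: 1.4, IFN-a: 1.3}
  novel-2:
    weight: 0.07
    mean: {FSC-A: 4.90, SSC-A: 4.40, CD123: 1.4, CD11c: 1.6, MHC-II: 1.8,
           CD14: 1.5, IL-6: 1.4, IL-12: 1.3, TNF-a: 1.4, IFN-a: 1.3}

# Detector crosstalk over the eight fluorescence channels, applied as
# observed = true . S.  Neighbouring detectors bleed the most.
spillover:
  adjacent: 0.06
  second: 0.015
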