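# cytostd

Open data standards for flow cytometry, implemented as one coherent
Python library and CLI.

In flow cytometry, cells in suspension pass a laser one at a time and a
bank of detectors records one intensity per channel per cell ("event").
The raw numbers live in **FCS** files, but a complete, reproducible
record of an experiment needs more: the *gates* used to select cell
populations, the (possibly fuzzy) *classification results* of manual or
automated analysis, and a *container* that bundles everything and
records how the files relate.  `cytostd` implements that full family of
formats:

| Layer | Format | What it captures |
|---|---|---|
| `cytostd.fcs` | FCS 3.1 (reads 2.0/3.0/3.1) | keyword metadata, per-channel descriptors, the n_events × n_channels event matrix |
| `cytostd.transforms` | flin / flog / fasinh / logicle / hyperlog | the display scales gate coordinates are expressed on |
| `cytostd.compensation` | $SPILLOVER / spectrum matrices | detector crosstalk and its inversion |
| `cytostd.gating` | Gating-ML XML | rectangle/polygon/ellipsoid/Boolean gates in a hierarchy, with vectorized evaluation |
| `cytostd.clr` | CLR CSV | per-event class-membership probabilities |
| `cytostd.acs` | ACS (ZIP + XML ToC) | the archival bundle and its relation graph |
| `cytostd.synth`, `cytostd.pipeline` | — | a seeded synthetic PBMC panel and the end-to-end example workflow |

The core semantics, briefly: a gate's population is its own geometric
predicate intersected with its parent's population; gate dimensions are
evaluated after per-dimension compensation (observed·S⁻¹ with events as
row vectors, S[i,j] the fraction of fluorochrome *i* seen in detector
*j*) and scale transformation (every transform maps its top-of-scale
value T to 1, e.g. fasinh(x) = (asinh(x·sinh(M ln10)/T) + A ln10) /
((M+A) ln10)); a CLR table assigns each event a probability per class;
an ACS container is valid when every table-of-contents entry resolves
to a member whose checksum matches and every relation names listed
members.

## Worked example

Build the two-sample example container — synthetic stimulated-PBMC data
(10 channels: FSC-A, SSC-A, CD123, CD11c, MHC-II, CD14, IL-6, IL-12,
TNF-a, IFN-a) taken through preprocessing, manual-style gating,
Gaussian-mixture clustering, cluster matching and comparison, then
bundled with a relation-bearing table of contents:

```sh
cytostd example build --seed 42 -o example.acs
# wrote example.acs (8 members + ToC)
cytostd acs graph example.acs
# fcs/preprocessed/sample1_pre.fcs --preprocessed-from--> fcs/original/sample1.fcs
# gating/sample1.gating-ml.xml --gating-description-of--> fcs/preprocessed/sample1_pre.fcs
# clr/sample1.clr.csv --classification-results-of--> fcs/preprocessed/sample1_pre.fcs
# ... (same three relations for sample2)
cytostd example verify example.acs   # replays gating, checks recorded counts
```

The same pipeline from Python, on one 20,000-event sample:

```python
>>> from cytostd.pipeline import run_sample
>>> art = run_sample(seed=42, n_events=20000, k=6)
>>> {g: s["count"] for g, s in art["stats"].items()}
{'live': 16867, 'monocytes': 5491, 'nonmono': 11376, 'pDC': 1468,
 'mDC': 1989, 'B cells': 4977}
>>> art["mapping"]
{'cluster-1': 'mDC', 'cluster-2': 'novel', 'cluster-3': 'monocytes',
 'cluster-4': 'B cells', 'cluster-5': 'novel', 'cluster-6': 'pDC'}
>>> round(art["comparison"].mean_f, 4)
0.9995
```

Reading: the live-cell scatter gate keeps 16,867 of 20,000 events (the
rest are the simulated debris/dead fraction); the fixed marker gates
then select monocytes (CD14-high), pDC (CD123-high), mDC (CD11c-high)
and B cells (MHC-II-high/CD11c-low).  Six-component Gaussian-mixture
clustering of the same preprocessed events, matched to the gated
populations by Hungarian assignment, reproduces them with a mean
F-measure of 0.9995; the two unmatched clusters are the deliberately
unannotated "novel" populations the generator plants.

Every subcommand (`cytostd fcs info/export`, `compensate`,
`gate apply`, `clr validate/assign`, `acs pack/unpack/validate/graph`,
`synth`, `example build/verify`) has `--help` text.

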