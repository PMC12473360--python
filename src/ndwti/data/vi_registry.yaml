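# Vegetation-index registry: name -> formula over the four band means
# {green, red, red_edge, nir} and numeric constants.  All entries are
# standard four-band multispectral indices from the remote-sensing
# literature; NDVI, RVI and OSAVI are the per-stage best performers for
# biomass and must stay present.
NDVI: (nir - red) / (nir + red)
RVI: nir / red
DVI: nir - red
OSAVI: (nir - red) / (nir + red + 0.16)
SAVI: 1.5 * (nir - red) / (nir + red + 0.5)
EVI2: 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)
RDVI: (nir - red) / sqrt(nir + red)
MSR: (nir / red - 1.0) / sqrt(nir / red + 1.0)
WDRVI: (0.12 * nir - red) / (0.12 * nir + red)
NLI: (nir * nir - red) / (nir * nir + red)
GNDVI: (nir - green) / (nir + green)
GRVI: nir / green
GOSAVI: (nir - green) / (nir + green + 0.16)
CIgreen: nir / green - 1.0
NDRE: (nir - red_edge) / (nir + red_edge)
RERVI: nir / red_edge
CIrededge: nir / red_edge - 1.0
RENDVI: (red_edge - red) / (red_edge + red)
MTCI: (nir - red_edge) / (red_edge - red)
MCARI: ((red_edge - red) - 0.2 * (red_edge - green)) * (red_edge / red)
TVI: 0.5 * (120.0 * (nir - green) - 200.0 * (red - green))
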