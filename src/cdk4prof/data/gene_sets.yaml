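# Signature gene sets (editable).
#
# provenance: reconstructed defaults.  The thyroid differentiation score
# (TDS) panel follows the 16-gene thyroid-identity list popularized by the
# TCGA thyroid study; the EMT panel follows the 13 mesenchymal / 4
# epithelial marker split of the cited EMT signature, with OCLN included
# among the epithelial markers.  Edit freely to match your local signature
# definitions -- scores are computed from whatever is listed here.
tds:
  - DIO1
  - DIO2
  - DUOX1
  - DUOX2
  - FOXE1
  - GLIS3
  - NKX2-1
  - PAX8
  - SLC26A4
  - SLC5A5
  - SLC5A8
  - TG
  - THRA
  - THRB
  - TPO
  - TSHR
emt:
  mesenchymal:
    - VIM
    - CDH2
    - FN1
    - SNAI1
    - SNAI2
    - TWIST1
    - ZEB1
    - ZEB2
    - MMP2
    - MMP3
    - MMP9
    - FOXC2
    - ITGB6
  epithelial:
    - CDH1
    - DSP
    - OCLN
    - TJP1
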