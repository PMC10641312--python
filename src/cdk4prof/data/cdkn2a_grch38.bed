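# CDKN2A locus annotation, GRCh38 (Ensembl-style coordinates, BED half-open).
# Default used by the exon-1alpha pipeline; override with any BED4 whose name
# field is one of exon1a / exon1b / shared_exon / intron.
chr9	21967751	21968241	shared_exon
chr9	21968241	21970900	intron
chr9	21970900	21971207	shared_exon
chr9	21971207	21974402	intron
chr9	21974402	21974827	exon1a
chr9	21974827	21994138	intron
chr9	21994138	21994454	exon1b
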