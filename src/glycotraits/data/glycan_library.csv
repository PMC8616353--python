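name,glycan_class,glycan_type,antennae,bisecting,core_fucose,antennary_fucose,sia_a23,sia_a26_gal,sia_a26_core,sia_a28,sia_unknown,lacnac_repeats,sulfo_sites,has_H_antigen,has_T_antigen,has_sLex_a,has_Lex_a
H2N2,N,paucimannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H2N2F1,N,paucimannose,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
H3N2,N,paucimannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H3N2F1,N,paucimannose,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
H4N2,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H5N2,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H6N2,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H7N2,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H8N2,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H9N2,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H5N2P1,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H6N2P1,N,oligomannose,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H4N3,N,hybrid,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H4N3S1,N,hybrid,1,0,0,0,1,0,0,0,0,0,0,0,0,0,0
H5N3S1,N,hybrid,1,0,0,0,0,1,0,0,0,0,0,0,0,0,0
H4N3F1S1a,N,hybrid,1,0,1,0,1,0,0,0,0,0,0,0,0,0,0
H4N3F1S1b,N,hybrid,1,0,1,0,0,1,0,0,0,0,0,0,0,0,0
H4N3F1S1c,N,hybrid,1,0,1,0,0,0,0,0,1,0,0,0,0,0,0
H3N4F1,N,complex,2,0,1,0,0,0,0,0,0,0,0,0,0,0,0
H4N4F1,N,complex,2,0,1,0,0,0,0,0,0,0,0,0,0,0,0
H5N4,N,complex,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H5N4F1,N,complex,2,0,1,0,0,0,0,0,0,0,0,0,0,0,0
H5N4S1,N,complex,2,0,0,0,1,0,0,0,0,0,0,0,0,0,0
H5N4S2a,N,complex,2,0,0,0,2,0,0,0,0,0,0,0,0,0,0
H5N4S2b,N,complex,2,0,0,0,1,1,0,0,0,0,0,0,0,0,0
H5N4F1S1,N,complex,2,0,1,0,0,1,0,0,0,0,0,0,0,0,0
H5N4F1S2,N,complex,2,0,1,0,1,1,0,0,0,0,0,0,0,0,0
H5N4F2,N,complex,2,0,1,1,0,0,0,0,0,0,0,0,0,0,1
H5N4F2S1,N,complex,2,0,1,1,1,0,0,0,0,0,0,0,0,1,0
H5N4F2S2,N,complex,2,0,1,1,2,0,0,0,0,0,0,0,0,1,0
H5N5F1,N,complex,2,1,1,0,0,0,0,0,0,0,0,0,0,0,0
H5N5F1S1,N,complex,2,1,1,0,0,1,0,0,0,0,0,0,0,0,0
H5N5S2,N,complex,2,1,0,0,1,1,0,0,0,0,0,0,0,0,0
H6N5S2,N,complex,3,0,0,0,1,1,0,0,0,0,0,0,0,0,0
H6N5S3,N,complex,3,0,0,0,2,1,0,0,0,0,0,0,0,0,0
H6N5F1S3,N,complex,3,0,0,1,2,0,0,0,1,0,0,0,0,1,0
H6N5F2S2,N,complex,3,0,1,1,1,0,0,0,1,0,0,0,0,1,0
H7N6S3,N,complex,4,0,0,0,2,0,0,0,1,0,0,0,0,0,0
H7N6S4,N,complex,4,0,0,0,0,0,0,0,4,0,0,0,0,0,0
H7N6F1S4,N,complex,4,0,0,1,0,0,0,0,4,0,0,0,0,1,0
H8N7S4,N,complex,3,0,0,0,2,1,0,0,1,1,0,0,0,0,0
H1N1,O,core1,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0
H1N1F1,O,core1,0,0,0,1,0,0,0,0,0,0,0,1,0,0,0
H1N1S1a,O,core1,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
H1N1S1b,O,core1,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
H1N1S2,O,core1,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0
H1N1S3,O,core1,0,0,0,0,1,0,1,1,0,0,0,0,0,0,0
H2N2,O,core2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
H2N2S1a,O,core2,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
H2N2S1b,O,core2,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
H2N2S2,O,core2,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0
H2N2S3,O,core2,0,0,0,0,1,0,1,1,0,0,0,0,0,0,0
H2N2F1a,O,core2,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
H2N2F1b,O,core2,0,0,0,1,0,0,0,0,0,0,0,1,0,0,0
H2N2F1S1,O,core2,0,0,0,1,1,0,0,0,0,0,0,0,0,1,0
H2N2F1S2,O,core2,0,0,0,1,1,0,1,0,0,0,0,0,0,1,0
H2N2Su1,O,core2,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0
H2N2S1Su1,O,core2,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0
H3N3S1,O,core2,0,0,0,0,1,0,0,0,0,1,0,0,0,0,0
H3N3F1,O,core2,0,0,0,1,0,0,0,0,0,1,0,0,0,0,1
H3N3F1S1,O,core2,0,0,0,1,1,0,0,0,0,1,0,0,0,1,0
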