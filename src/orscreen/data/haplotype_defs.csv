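gene,haplotype,sites,maf_pct,freq_pct,functional
OR10A6,ref,,,21.81,False
OR10A6,V140G,rs7933807,41.3,,False
OR10A6,A117V,rs7928451,39.4,0.08,False
OR10A6,L287P,rs4758258,21.2,35.02,True
OR10A6,A117V/V140G/L287P,rs7928451;rs7933807;rs4758258,,37.33,False
OR10A6,V140G/L287P,rs7933807;rs4758258,,1.92,False
OR10A6,A117V/L287P,rs7928451;rs4758258,,0.15,False
OR2W1,ref,,,72.43,True
OR2W1,M81V,rs34892006,3.9,3.61,True
OR2W1,D296N,rs35771565,24.9,23.96,True
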