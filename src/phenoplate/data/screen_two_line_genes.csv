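locus,family,locus_name,superfamily,category_reported,stress,line_rank,value,p_adj,year
At1g21260,,,LTR,6,arsenic,1,26,1.20e-07,
At1g21260,,,LTR,6,arsenic,2,38,4.89e-04,
At2g27110,FRS3,FRS3,MULE,1,arsenic,1,88,1.94e-04,
At2g27110,FRS3,FRS3,MULE,1,arsenic,2,47,3.58e-02,
At1g06740,MUGA,MUG3,MULE,6,salt,1,43,1.34e-03,
At1g06740,MUGA,MUG3,MULE,6,salt,2,50,2.73e-02,
At1g15300,,,hAT,6,salt,1,43,1.34e-03,
At1g15300,,,hAT,6,salt,2,43,1.34e-03,
At1g64255,,,MULE,6,salt,1,28,2.37e-07,
At1g64255,,,MULE,6,salt,2,48,1.06e-02,
At1g69950,,,hAT,6,salt,1,15,6.45e-13,
At1g69950,,,hAT,6,salt,2,29,3.58e-07,
At1g69950,,,hAT,6,salt,3,36,2.28e-05,
At1g69950,,,hAT,6,freezing,1,41,8.59e-05,2013
At1g80020,,,hAT,6,salt,1,25,1.82e-08,
At1g80020,,,hAT,6,salt,2,34,1.16e-05,
At1g80020,,,hAT,6,salt,3,47,1.06e-02,
At1g80020,,,hAT,6,freezing,1,87,2.60e-05,2011
At1g80020,,,hAT,6,freezing,2,47,1.15e-03,2013
At2g30640,MUGA,MUG2,MULE,6,salt,1,27,7.55e-08,
At2g30640,MUGA,MUG2,MULE,6,salt,2,32,8.95e-06,
At2g30640,MUGA,MUG2,MULE,6,arsenic,1,6,2.66e-19,
At2g30640,MUGA,MUG2,MULE,6,arsenic,2,8,2.69e-17,
At3g04605,MUGA,MUG1,MULE,6,salt,1,21,4.15e-10,
At3g04605,MUGA,MUG1,MULE,6,salt,2,22,1.04e-09,
At3g04605,MUGA,MUG1,MULE,6,arsenic,1,14,2.00e-13,
At3g04605,MUGA,MUG1,MULE,6,arsenic,2,17,1.66e-09,
At3g13020,,,hAT,6,salt,1,39,3.15e-04,
At3g13020,,,hAT,6,salt,2,40,3.62e-04,
At3g13020,,,hAT,6,salt,3,50,2.04e-02,
At3g13020,,,hAT,6,arsenic,1,37,4.89e-04,
At3g13020,,,hAT,6,arsenic,2,46,3.59e-02,
At3g13030,,,hAT,6,salt,1,35,2.16e-05,
At3g13030,,,hAT,6,salt,2,47,1.06e-02,
At3g13030,,,hAT,6,salt,3,49,1.47e-02,
At3g13030,,,hAT,6,phosphate,1,513.87,5.91e-03,
At3g13030,,,hAT,6,phosphate,2,451.20,2.57e-02,
At3g13030,,,hAT,6,phosphate,3,409.42,2.99e-02,
At3g17450,,,hAT,6,salt,1,35,2.16e-05,
At3g17450,,,hAT,6,salt,2,49,2.04e-02,
At3g17450,,,hAT,6,phosphate,1,679.03,5.41e-06,
At3g17450,,,hAT,6,phosphate,2,552.01,3.42e-03,
At3g22170,FHY3,FHY3/CPD45,MULE,6,salt,1,26,4.02e-08,
At3g22170,FHY3,FHY3/CPD45,MULE,6,salt,2,31,1.60e-06,
At3g22220,,,hAT,6,salt,1,46,7.79e-03,
At3g22220,,,hAT,6,salt,2,50,2.82e-02,
At3g22220,,,hAT,6,phosphate,1,490.36,8.83e-03,
At3g22220,,,hAT,6,phosphate,2,391.97,4.95e-02,
At3g55350,,,PIF-Harbinger,6,salt,1,23,7.96e-09,
At3g55350,,,PIF-Harbinger,6,salt,2,41,5.39e-04,
At3g55350,,,PIF-Harbinger,6,arsenic,1,10,6.28e-16,
At3g55350,,,PIF-Harbinger,6,arsenic,2,15,6.42e-13,
At4g13120,,,hAT,6,salt,1,10,1.51e-16,
At4g13120,,,hAT,6,salt,2,41,5.44e-04,
At4g13120,,,hAT,6,salt,3,43,1.34e-03,
At4g13120,,,hAT,6,phosphate,1,563.49,6.04e-03,
At4g13120,,,hAT,6,phosphate,2,445.79,2.67e-02,
At4g19990,FHY3,FRS1,MULE,6,salt,1,40,5.44e-04,
At4g19990,FHY3,FRS1,MULE,6,salt,2,48,1.45e-02,
At4g19990,FHY3,FRS1,MULE,6,salt,3,49,1.47e-02,
At4g19990,FHY3,FRS1,MULE,6,arsenic,1,37,4.89e-04,
At4g19990,FHY3,FRS1,MULE,6,arsenic,2,40,1.34e-03,
At4g19990,FHY3,FRS1,MULE,6,phosphate,1,554.35,2.25e-05,
At4g19990,FHY3,FRS1,MULE,6,phosphate,2,470.36,6.04e-03,
At5g16505,MUGA,MUG4,MULE,6,salt,1,13,2.67e-14,
At5g16505,MUGA,MUG4,MULE,6,salt,2,19,3.47e-11,
At1g10240,FRS10,FRS11,MULE,6,phosphate,1,483.80,6.04e-03,
At1g10240,FRS10,FRS11,MULE,6,phosphate,2,483.14,9.04e-03,
At1g52520,FRS6,FRS6,MULE,6,phosphate,1,506.89,8.31e-04,
At1g52520,FRS6,FRS6,MULE,6,phosphate,2,442.00,1.28e-02,
At1g76320,FHY3,FRS4/CPD25,MULE,6,phosphate,1,452.98,2.97e-03,
At1g76320,FHY3,FRS4/CPD25,MULE,6,phosphate,2,444.35,3.53e-03,
At3g06250,FRS7,FRS7,MULE,6,salt,1,27,4.13e-07,
At3g06250,FRS7,FRS7,MULE,6,salt,2,35,1.37e-05,
At5g34853,MUGB,MUG8,MULE,6,freezing,1,17,1.07e-03,2011
At5g34853,MUGB,MUG8,MULE,6,freezing,2,19,1.10e-03,2011
At5g34853,MUGB,MUG8,MULE,6,freezing,3,47,1.15e-03,2013
At5g41980,,,,6,salt,1,16,5.40e-09,
At5g41980,,,,6,salt,2,46,7.79e-03,
At5g50315,,,,6,salt,1,34,1.90e-05,
At5g50315,,,,6,salt,2,38,1.15e-04,
At5g50315,,,,6,arsenic,1,23,9.42e-09,
At5g50315,,,,6,arsenic,2,34,3.23e-05,
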