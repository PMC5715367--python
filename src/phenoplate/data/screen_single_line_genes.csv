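locus,family,locus_name,superfamily,category_reported,stress,line_rank,value,p_adj,year
At3g06940,MUGB,MUG5,MULE,3,salt,1,31,1.60e-06,
At3g06940,MUGB,MUG5,MULE,3,arsenic,1,29,1.09e-06,
At3g13010,,,hAT,3,salt,1,38,1.20e-04,
At3g13010,,,hAT,3,arsenic,1,36,8.57e-04,
At4g15090,FHY3,FAR1,MULE,3,salt,1,43,1.34e-03,
At4g15090,FHY3,FAR1,MULE,3,arsenic,1,40,1.34e-03,
At4g15090,FHY3,FAR1,MULE,3,phosphate,1,524.58,6.79e-04,
At4g38170,FRS3,FRS9,MULE,3,salt,1,44,4.00e-03,
At4g38170,FRS3,FRS9,MULE,3,arsenic,1,28,5.47e-07,
At5g48965,MUGB,MUG6,MULE,1,salt,1,46,5.33e-03,
At5g20880,,,LTR,3,salt,1,47,7.79e-03,
At5g20880,,,LTR,3,phosphate,1,495.58,7.30e-03,
At3g17290,,,hAT,1,salt,1,47,1.06e-02,
At5g28530,FRS10,FRS10,MULE,3,salt,1,49,2.03e-02,
At5g28530,FRS10,FRS10,MULE,3,phosphate,1,474.69,1.63e-02,
At1g79740,,,hAT,3,phosphate,1,543.92,4.59e-05,
At2g32250,FHY3,FRS2,MULE,1,phosphate,1,545.35,6.04e-03,
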