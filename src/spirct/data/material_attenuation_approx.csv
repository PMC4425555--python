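# Approximate linear attenuation (1/cm) of phantom materials, 20-120 keV.
# Synthetic anchor table assembled from rounded NIST-style mass attenuation
# values times nominal densities (water 1.00, soft tissue 1.06, cortical
# bone 1.92, marrow 0.98, tooth/dentin 2.2 g/cm^3).  The phantom is defined
# by the least-squares projection of these curves onto the photoelectric and
# Klein-Nishina bases, so only the overall shape matters.
energy_keV,water,soft_tissue,bone_cortical,marrow,tooth
20,0.8096,0.8697,7.682,0.5361,8.802
30,0.3756,0.4010,2.556,0.2979,2.928
40,0.2683,0.2846,1.278,0.2348,1.464
50,0.2269,0.2398,0.8145,0.2081,0.9332
60,0.2059,0.2171,0.6044,0.1935,0.6926
70,0.1932,0.2033,0.5007,0.1833,0.5738
80,0.1837,0.1932,0.4280,0.1751,0.4904
90,0.1769,0.1859,0.3878,0.1686,0.4444
100,0.1707,0.1795,0.3562,0.1632,0.4081
110,0.1660,0.1744,0.3377,0.1586,0.3870
120,0.1620,0.1701,0.3218,0.1545,0.3687
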