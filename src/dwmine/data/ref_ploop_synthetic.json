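{
 "source": "synthetic stand-in: idealized 14-residue P-loop fragment built from region-center torsions spelling BBBEBBGAGAAAAA (not derived from any experimental structure)",
 "ca_coords": [
  [
   1.8682,
   3.6626,
   -0.942
  ],
  [
   0.0014,
   6.5507,
   0.684
  ],
  [
   -0.1027,
   10.1075,
   -0.6607
  ],
  [
   -1.3928,
   13.1251,
   1.2629
  ],
  [
   -3.211,
   13.1086,
   4.6041
  ],
  [
   -6.9562,
   12.6068,
   5.0419
  ],
  [
   -8.8742,
   13.2339,
   8.2665
  ],
  [
   -5.6025,
   14.3805,
   9.8322
  ],
  [
   -7.2038,
   17.5591,
   11.1748
  ],
  [
   -3.7284,
   19.101,
   11.2915
  ],
  [
   -4.9089,
   22.2285,
   9.4762
  ],
  [
   -7.8242,
   22.6838,
   11.877
  ],
  [
   -5.5485,
   22.3777,
   14.9098
  ],
  [
   -3.1388,
   24.9784,
   13.5315
  ]
 ]
}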