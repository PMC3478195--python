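# Synthetic default ACE parameter set.
# Placeholder contact energies generated from a per-type apolar propensity
# (T[i,j] = -1.5*(p_i + p_j) + symmetric jitter); replace with a real
# 18-type statistical table for production scoring.  The typing map
# covers the heavy atoms of the 20 standard residues.
TYPES N CA C O GCA CB CAL KNZ KCE OCX CCX NAM CAM RGN OHX NHS CAR S
ENERGY 0 0 1.825
ENERGY 0 1 0.803
ENERGY 0 2 1.293
ENERGY 0 3 1.926
ENERGY 0 4 0.794
ENERGY 0 5 0.218
ENERGY 0 6 -0.541
ENERGY 0 7 2.387
ENERGY 0 8 0.395
ENERGY 0 9 2.356
ENERGY 0 10 1.559
ENERGY 0 11 2.085
ENERGY 0 12 1.332
ENERGY 0 13 2.32
ENERGY 0 14 2.093
ENERGY 0 15 1.938
ENERGY 0 16 -0.356
ENERGY 0 17 -0.039
ENERGY 1 1 -0.296
ENERGY 1 2 0.361
ENERGY 1 3 0.918
ENERGY 1 4 -0.108
ENERGY 1 5 -0.918
ENERGY 1 6 -1.461
ENERGY 1 7 1.389
ENERGY 1 8 -0.573
ENERGY 1 9 1.305
ENERGY 1 10 0.479
ENERGY 1 11 1.036
ENERGY 1 12 0.349
ENERGY 1 13 1.181
ENERGY 1 14 1.076
ENERGY 1 15 0.944
ENERGY 1 16 -1.335
ENERGY 1 17 -1.098
ENERGY 2 2 0.853
ENERGY 2 3 1.505
ENERGY 2 4 0.427
ENERGY 2 5 -0.354
ENERGY 2 6 -0.818
ENERGY 2 7 2.052
ENERGY 2 8 0.009
ENERGY 2 9 1.934
ENERGY 2 10 1.09
ENERGY 2 11 1.668
ENERGY 2 12 0.877
ENERGY 2 13 1.824
ENERGY 2 14 1.768
ENERGY 2 15 1.536
ENERGY 2 16 -0.815
ENERGY 2 17 -0.351
ENERGY 3 3 1.949
ENERGY 3 4 1.043
ENERGY 3 5 0.322
ENERGY 3 6 -0.27
ENERGY 3 7 2.503
ENERGY 3 8 0.599
ENERGY 3 9 2.579
ENERGY 3 10 1.534
ENERGY 3 11 2.125
ENERGY 3 12 1.49
ENERGY 3 13 2.439
ENERGY 3 14 2.284
ENERGY 3 15 2.071
ENERGY 3 16 -0.183
ENERGY 3 17 0.155
ENERGY 4 4 0.098
ENERGY 4 5 -0.787
ENERGY 4 6 -1.381
ENERGY 4 7 1.492
ENERGY 4 8 -0.441
ENERGY 4 9 1.474
ENERGY 4 10 0.612
ENERGY 4 11 1.22
ENERGY 4 12 0.549
ENERGY 4 13 1.305
ENERGY 4 14 1.186
ENERGY 4 15 1.058
ENERGY 4 16 -1.248
ENERGY 4 17 -0.929
ENERGY 5 5 -1.674
ENERGY 5 6 -2.123
ENERGY 5 7 0.837
ENERGY 5 8 -1.202
ENERGY 5 9 0.764
ENERGY 5 10 -0.131
ENERGY 5 11 0.419
ENERGY 5 12 -0.299
ENERGY 5 13 0.561
ENERGY 5 14 0.532
ENERGY 5 15 0.302
ENERGY 5 16 -1.977
ENERGY 5 17 -1.661
ENERGY 6 6 -2.643
ENERGY 6 7 0.044
ENERGY 6 8 -1.787
ENERGY 6 9 0.321
ENERGY 6 10 -0.817
ENERGY 6 11 -0.064
ENERGY 6 12 -0.962
ENERGY 6 13 0.016
ENERGY 6 14 -0.262
ENERGY 6 15 -0.317
ENERGY 6 16 -2.552
ENERGY 6 17 -2.274
ENERGY 7 7 2.981
ENERGY 7 8 0.972
ENERGY 7 9 3.106
ENERGY 7 10 2.075
ENERGY 7 11 2.664
ENERGY 7 12 1.873
ENERGY 7 13 2.815
ENERGY 7 14 2.734
ENERGY 7 15 2.598
ENERGY 7 16 0.334
ENERGY 7 17 0.683
ENERGY 8 8 -0.818
ENERGY 8 9 0.993
ENERGY 8 10 0.198
ENERGY 8 11 0.682
ENERGY 8 12 0.061
ENERGY 8 13 1.012
ENERGY 8 14 0.798
ENERGY 8 15 0.611
ENERGY 8 16 -1.619
ENERGY 8 17 -1.357
ENERGY 9 9 3.042
ENERGY 9 10 1.976
ENERGY 9 11 2.594
ENERGY 9 12 1.951
ENERGY 9 13 2.817
ENERGY 9 14 2.66
ENERGY 9 15 2.587
ENERGY 9 16 0.351
ENERGY 9 17 0.547
ENERGY 10 10 1.333
ENERGY 10 11 1.727
ENERGY 10 12 1.045
ENERGY 10 13 1.869
ENERGY 10 14 1.813
ENERGY 10 15 1.691
ENERGY 10 16 -0.663
ENERGY 10 17 -0.329
ENERGY 11 11 2.41
ENERGY 11 12 1.655
ENERGY 11 13 2.49
ENERGY 11 14 2.478
ENERGY 11 15 2.26
ENERGY 11 16 0.03
ENERGY 11 17 0.249
ENERGY 12 12 0.835
ENERGY 12 13 1.699
ENERGY 12 14 1.656
ENERGY 12 15 1.541
ENERGY 12 16 -0.658
ENERGY 12 17 -0.527
ENERGY 13 13 2.63
ENERGY 13 14 2.57
ENERGY 13 15 2.385
ENERGY 13 16 0.148
ENERGY 13 17 0.396
ENERGY 14 14 2.397
ENERGY 14 15 2.215
ENERGY 14 16 0.1
ENERGY 14 17 0.292
ENERGY 15 15 2.026
ENERGY 15 16 -0.143
ENERGY 15 17 0.105
ENERGY 16 16 -2.4
ENERGY 16 17 -2.041
ENERGY 17 17 -1.818
MAP ALA C 2
MAP ALA CA 1
MAP ALA CB 5
MAP ALA N 0
MAP ALA O 3
MAP ALA OXT 3
MAP ARG C 2
MAP ARG CA 1
MAP ARG CB 5
MAP ARG CD 6
MAP ARG CG 6
MAP ARG CZ 13
MAP ARG N 0
MAP ARG NE 13
MAP ARG NH1 13
MAP ARG NH2 13
MAP ARG O 3
MAP ARG OXT 3
MAP ASN C 2
MAP ASN CA 1
MAP ASN CB 5
MAP ASN CG 12
MAP ASN N 0
MAP ASN ND2 11
MAP ASN O 3
MAP ASN OD1 3
MAP ASN OXT 3
MAP ASP C 2
MAP ASP CA 1
MAP ASP CB 5
MAP ASP CG 10
MAP ASP N 0
MAP ASP O 3
MAP ASP OD1 9
MAP ASP OD2 9
MAP ASP OXT 3
MAP CYS C 2
MAP CYS CA 1
MAP CYS CB 5
MAP CYS N 0
MAP CYS O 3
MAP CYS OXT 3
MAP CYS SG 17
MAP GLN C 2
MAP GLN CA 1
MAP GLN CB 5
MAP GLN CD 12
MAP GLN CG 6
MAP GLN N 0
MAP GLN NE2 11
MAP GLN O 3
MAP GLN OE1 3
MAP GLN OXT 3
MAP GLU C 2
MAP GLU CA 1
MAP GLU CB 5
MAP GLU CD 10
MAP GLU CG 6
MAP GLU N 0
MAP GLU O 3
MAP GLU OE1 9
MAP GLU OE2 9
MAP GLU OXT 3
MAP GLY C 2
MAP GLY CA 4
MAP GLY N 0
MAP GLY O 3
MAP GLY OXT 3
MAP HIS C 2
MAP HIS CA 1
MAP HIS CB 5
MAP HIS CD2 16
MAP HIS CE1 16
MAP HIS CG 16
MAP HIS N 0
MAP HIS ND1 15
MAP HIS NE2 15
MAP HIS O 3
MAP HIS OXT 3
MAP ILE C 2
MAP ILE CA 1
MAP ILE CB 5
MAP ILE CD1 6
MAP ILE CG1 6
MAP ILE CG2 6
MAP ILE N 0
MAP ILE O 3
MAP ILE OXT 3
MAP LEU C 2
MAP LEU CA 1
MAP LEU CB 5
MAP LEU CD1 6
MAP LEU CD2 6
MAP LEU CG 6
MAP LEU N 0
MAP LEU O 3
MAP LEU OXT 3
MAP LYS C 2
MAP LYS CA 1
MAP LYS CB 5
MAP LYS CD 6
MAP LYS CE 8
MAP LYS CG 6
MAP LYS N 0
MAP LYS NZ 7
MAP LYS O 3
MAP LYS OXT 3
MAP MET C 2
MAP MET CA 1
MAP MET CB 5
MAP MET CE 6
MAP MET CG 6
MAP MET N 0
MAP MET O 3
MAP MET OXT 3
MAP MET SD 17
MAP PHE C 2
MAP PHE CA 1
MAP PHE CB 5
MAP PHE CD1 16
MAP PHE CD2 16
MAP PHE CE1 16
MAP PHE CE2 16
MAP PHE CG 16
MAP PHE CZ 16
MAP PHE N 0
MAP PHE O 3
MAP PHE OXT 3
MAP PRO C 2
MAP PRO CA 1
MAP PRO CB 5
MAP PRO CD 6
MAP PRO CG 6
MAP PRO N 0
MAP PRO O 3
MAP PRO OXT 3
MAP SER C 2
MAP SER CA 1
MAP SER CB 5
MAP SER N 0
MAP SER O 3
MAP SER OG 14
MAP SER OXT 3
MAP THR C 2
MAP THR CA 1
MAP THR CB 5
MAP THR CG2 6
MAP THR N 0
MAP THR O 3
MAP THR OG1 14
MAP THR OXT 3
MAP TRP C 2
MAP TRP CA 1
MAP TRP CB 5
MAP TRP CD1 16
MAP TRP CD2 16
MAP TRP CE2 16
MAP TRP CE3 16
MAP TRP CG 16
MAP TRP CH2 16
MAP TRP CZ2 16
MAP TRP CZ3 16
MAP TRP N 0
MAP TRP NE1 15
MAP TRP O 3
MAP TRP OXT 3
MAP TYR C 2
MAP TYR CA 1
MAP TYR CB 5
MAP TYR CD1 16
MAP TYR CD2 16
MAP TYR CE1 16
MAP TYR CE2 16
MAP TYR CG 16
MAP TYR CZ 16
MAP TYR N 0
MAP TYR O 3
MAP TYR OH 14
MAP TYR OXT 3
MAP VAL C 2
MAP VAL CA 1
MAP VAL CB 5
MAP VAL CG1 6
MAP VAL CG2 6
MAP VAL N 0
MAP VAL O 3
MAP VAL OXT 3
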