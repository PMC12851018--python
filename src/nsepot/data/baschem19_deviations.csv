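reaction,tpss_d3,b3lyp_d3bj,gfn2_xtb,aimnet2_nse
1,-4.07,-1.01,-5.73,-0.97
2,-4.09,0.25,-12.63,1.83
3,-7.61,-1.19,-10.92,3.20
4,-8.88,-4.83,14.96,-1.41
5,-6.48,-2.84,5.34,3.38
6,-6.79,-0.63,-8.44,2.56
7,-6.57,-2.44,4.96,2.53
8,-9.05,-3.29,0.09,6.71
9,-5.85,-3.30,-2.61,4.07
10,-6.24,-2.76,-21.97,-0.22
11,-3.93,-1.67,-10.59,1.66
12,-13.08,-5.50,-8.97,-0.01
13,-14.41,-5.09,-45.14,-3.72
14,-10.23,-6.39,10.54,7.91
15,-5.39,-0.78,-1.32,0.37
16,-2.19,-0.89,7.81,-0.59
17,-2.05,-0.95,2.52,-0.56
18,-0.21,-1.67,8.27,0.30
19,-6.98,-3.07,-10.50,2.48
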