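subdataset,images,total,N,L,F,B,LF,BL,BF,BLF
ZY_H,2738,36803,9856,5597,1296,10579,474,6405,1936,660
ZY_L,2132,25165,9639,4558,901,5671,252,3133,728,283
QX_H,2681,8159,1273,804,268,3053,116,1442,934,269
QX_L,146,491,68,34,6,215,0,112,41,15
PSR_H,1558,10774,2150,5295,540,189,1457,942,54,147
PSR_L,0,0,0,0,0,0,0,0,0,0
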