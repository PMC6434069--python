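mutation,gene,predictor,ddg,table
F162L,PDE6A,mCSM,-1.381,stability
F162L,PDE6A,SDM2,-1.95,stability
F162L,PDE6A,DUET,-1.492,stability
F162L,PDE6A,mCSM-PPI,-1.027,stability
F162L,PDE6A,mCSM-NA,-0.549,stability
V141M,PDE6A,mCSM,-0.951,stability
V141M,PDE6A,SDM2,-0.98,stability
V141M,PDE6A,DUET,-0.61,stability
V141M,PDE6A,mCSM-PPI,-1.576,stability
V141M,PDE6A,mCSM-NA,-4.978,stability
R93L,PDE6A,mCSM,-1.211,stability
R93L,PDE6A,SDM2,-1.01,stability
R93L,PDE6A,DUET,-1.297,stability
R93L,PDE6A,mCSM-PPI,-1.358,stability
R93L,PDE6A,mCSM-NA,-2.222,stability
D600N,PDE6A,mCSM,-1.011,stability
D600N,PDE6A,SDM2,-0.934,stability
D600N,PDE6A,DUET,-1.554,stability
D600N,PDE6A,mCSM-PPI,-1.287,stability
D600N,PDE6A,mCSM-NA,-3.088,stability
F742L,PDE6A,mCSM,-1.751,stability
F742L,PDE6A,SDM2,-0.872,stability
F742L,PDE6A,DUET,-0.706,stability
F742L,PDE6A,mCSM-PPI,-1.512,stability
F742L,PDE6A,mCSM-NA,-1.702,stability
F776L,PDE6A,mCSM,-1.504,stability
F776L,PDE6A,SDM2,-0.72,stability
F776L,PDE6A,DUET,-0.706,stability
F776L,PDE6A,mCSM-PPI,-1.281,stability
F776L,PDE6A,mCSM-NA,-1.702,stability
F426A,PDE6A,mCSM-PPI,-2.548,interface
F249G,PDE6A,mCSM-PPI,-1.288,interface
F424N,PDE6B,mCSM-PPI,-1.591,interface
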