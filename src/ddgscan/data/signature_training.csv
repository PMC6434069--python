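mode,chain,position,wt,mut,rsa,label
ligand,A,50,S,N,1.2336,0.0896
ligand,A,30,H,S,1.2442,-0.4272
ligand,A,10,S,G,1.1802,-0.2975
ligand,A,50,S,A,1.2336,0.4021
ligand,A,10,S,T,1.1802,-0.1861
ligand,A,50,S,G,1.2336,0.1071
ligand,A,40,L,F,1.1555,-0.2791
ligand,A,30,H,M,1.2442,0.2086
ligand,A,30,H,Y,1.2442,-0.2973
ligand,A,40,L,P,1.1555,-0.7069
ligand,A,30,H,F,1.2442,-0.0705
ligand,A,50,S,N,1.2336,0.0814
ligand,A,30,H,A,1.2442,-0.2161
ligand,A,50,S,K,1.2336,-0.6816
ligand,A,50,S,N,1.2336,0.034
ligand,A,20,F,M,0.9564,-0.1622
ligand,A,10,S,E,1.1802,-0.6427
ligand,A,50,S,E,1.2336,-0.7623
ligand,A,30,H,A,1.2442,0.1053
ligand,A,40,L,D,1.1555,-0.3535
ligand,A,50,S,V,1.2336,-0.5009
ligand,A,50,S,V,1.2336,-0.4972
ligand,A,10,S,R,1.1802,-0.8641
ligand,A,20,F,N,0.9564,-0.5368
ligand,A,40,L,V,1.1555,0.6001
ligand,A,40,L,P,1.1555,-0.6798
ligand,A,40,L,I,1.1555,0.173
ligand,A,20,F,D,0.9564,-0.3889
ligand,A,30,H,K,1.2442,0.2002
ligand,A,20,F,P,0.9564,-0.7661
ligand,A,30,H,Q,1.2442,-0.139
ligand,A,50,S,D,1.2336,-0.3562
ligand,A,20,F,G,0.9564,-0.6435
ligand,A,50,S,C,1.2336,0.3436
ligand,A,50,S,F,1.2336,-0.7584
ligand,A,10,S,G,1.1802,-0.5977
ligand,A,10,S,P,1.1802,-0.0292
ligand,A,50,S,V,1.2336,-0.3132
ligand,A,40,L,W,1.1555,-0.4306
ligand,A,20,F,D,0.9564,-0.1367
ligand,A,40,L,W,1.1555,-0.4111
ligand,A,10,S,E,1.1802,-0.4362
ligand,A,50,S,P,1.2336,-0.3342
ligand,A,10,S,I,1.1802,-0.5331
ligand,A,20,F,G,0.9564,-0.3887
ligand,A,50,S,V,1.2336,-0.3195
ligand,A,40,L,N,1.1555,-0.0044
ligand,A,30,H,S,1.2442,0.015
ligand,A,40,L,I,1.1555,0.104
ligand,A,50,S,D,1.2336,-0.6106
ligand,A,10,S,P,1.1802,-0.27
ligand,A,10,S,L,1.1802,0.2734
ligand,A,40,L,H,1.1555,-0.1872
ligand,A,20,F,Q,0.9564,-0.4092
ligand,A,50,S,L,1.2336,-0.5818
ligand,A,40,L,W,1.1555,-0.164
ligand,A,30,H,W,1.2442,-0.1838
ligand,A,30,H,S,1.2442,-0.4763
ligand,A,40,L,D,1.1555,-0.5774
ligand,A,50,S,T,1.2336,0.0578
ligand,A,50,S,N,1.2336,-0.1773
ligand,A,50,S,L,1.2336,-1.1193
ligand,A,20,F,G,0.9564,-0.4758
ligand,A,50,S,H,1.2336,-0.266
ligand,A,20,F,I,0.9564,0.2149
ligand,A,50,S,M,1.2336,-0.2863
ligand,A,10,S,G,1.1802,-0.4611
ligand,A,20,F,L,0.9564,0.4204
ligand,A,10,S,L,1.1802,-0.4822
ligand,A,50,S,W,1.2336,-0.8125
ligand,A,30,H,P,1.2442,-0.3229
ligand,A,50,S,V,1.2336,-0.758
ligand,A,40,L,W,1.1555,-0.7033
ligand,A,20,F,L,0.9564,-0.0584
ligand,A,30,H,Y,1.2442,-0.156
ligand,A,40,L,T,1.1555,-0.418
ligand,A,20,F,R,0.9564,-0.0641
ligand,A,20,F,I,0.9564,-0.1021
ligand,A,40,L,E,1.1555,-0.2421
ligand,A,30,H,F,1.2442,-0.2014
ppi,B,12,G,T,0.5076,-0.2474
ppi,B,15,G,M,0.5033,-1.3089
ppi,A,17,G,Q,0.685,-0.6432
ppi,A,5,G,Y,0.4325,-0.8099
ppi,A,9,G,P,0.4169,-0.4906
ppi,A,4,G,E,0.5531,-0.6508
ppi,B,7,G,K,0.2116,-1.8353
ppi,B,8,S,T,0.6401,-0.4819
ppi,B,13,G,D,0.5068,-1.0994
ppi,B,7,G,T,0.2116,-0.6483
ppi,B,15,G,M,0.5033,-1.0251
ppi,A,11,G,A,0.4909,-0.2647
ppi,A,16,G,A,0.3534,-0.2145
ppi,B,8,S,F,0.6401,-0.4316
ppi,B,17,G,N,0.6424,-0.7538
ppi,A,12,G,P,0.3263,-0.5174
ppi,A,5,G,Q,0.4325,-0.8833
ppi,A,17,G,H,0.685,-0.3143
ppi,B,13,G,N,0.5068,-0.4667
ppi,A,16,G,Q,0.3534,-0.7354
ppi,A,9,G,E,0.4169,-0.8286
ppi,A,14,F,A,0.6953,-0.8449
ppi,A,17,G,Y,0.685,-0.1134
ppi,A,1,G,A,1.0102,-0.5066
ppi,B,13,G,I,0.5068,-1.1755
ppi,A,11,G,P,0.4909,-0.1427
ppi,A,11,G,H,0.4909,-1.4874
ppi,A,16,G,T,0.3534,-0.7444
ppi,B,12,G,S,0.5076,-0.1828
ppi,A,18,G,E,0.9761,-0.4961
ppi,A,14,F,Q,0.6953,-1.3904
ppi,B,11,G,C,0.3908,-0.5021
ppi,A,2,G,Q,0.6392,-0.3746
ppi,B,7,G,T,0.2116,-0.8356
ppi,A,4,G,R,0.5531,-1.2945
ppi,A,17,G,V,0.685,-0.557
ppi,A,13,G,A,0.3969,-0.1043
ppi,B,6,G,F,0.4727,-1.2791
ppi,B,5,G,W,0.4879,-1.0881
ppi,A,6,G,F,0.4727,-1.2563
ppi,B,18,G,Q,0.9083,-0.1633
ppi,B,4,G,K,0.5497,-1.0138
ppi,A,7,G,Q,0.4879,-0.3585
ppi,B,1,G,K,1.0102,-0.6601
ppi,B,6,G,N,0.4727,-1.1685
ppi,B,8,S,F,0.6401,-0.8415
ppi,B,13,G,L,0.5068,-0.4709
ppi,A,13,G,S,0.3969,-0.5899
ppi,B,14,F,H,0.3785,-0.5218
ppi,A,8,S,R,0.7699,-0.8844
ppi,B,1,G,D,1.0102,0.0115
ppi,B,6,G,C,0.4727,-0.1805
ppi,B,9,G,H,0.4964,-1.158
ppi,B,10,G,T,0.405,-0.8465
ppi,B,13,G,E,0.5068,-1.4902
ppi,A,7,G,V,0.4879,-0.4932
ppi,A,12,G,R,0.3263,-1.314
ppi,B,6,G,R,0.4727,-1.3927
ppi,B,2,G,T,0.6392,-0.1418
ppi,A,13,G,K,0.3969,-1.4948
ppi,A,9,G,M,0.4169,-0.7543
ppi,B,12,G,E,0.5076,-0.9482
ppi,B,9,G,N,0.4964,-0.1573
ppi,B,5,G,W,0.4879,-1.0629
ppi,B,14,F,E,0.3785,-1.8201
ppi,A,17,G,Q,0.685,-0.9986
ppi,A,15,G,Y,0.5212,-0.5294
ppi,B,11,G,V,0.3908,-0.6835
ppi,B,4,G,K,0.5497,-0.9734
ppi,A,8,S,E,0.7699,-0.8356
ppi,B,4,G,S,0.5497,0.2758
ppi,A,8,S,K,0.7699,-0.8865
ppi,A,13,G,K,0.3969,-1.7604
ppi,A,13,G,V,0.3969,-0.6862
ppi,A,4,G,K,0.5531,-1.0745
ppi,A,1,G,R,1.0102,-0.0201
ppi,A,2,G,T,0.6392,-0.3732
ppi,A,14,F,K,0.6953,-0.5263
ppi,A,2,G,S,0.6392,-0.6203
ppi,A,5,G,D,0.4325,-1.1301
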