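y,steam,temp,w
0.9378938819,1,0,2.842525218
0.9904632198,1.5,0,1.053528046
0.9801947717,2.5,0,0.7154628615
0.9658602907,4,0,-0.8734335815
0.8962223048,6,0,1.022935167
0.8379174447,10,0,1.678494694
0.9217762404,24,0,-0.1439205997
0.9917088429,1,0,0.9945251495
0.943358608,1.5,0,1.782714469
0.9515525929,2.5,0,1.382762269
0.9607000502,4,0,0.6345633354
0.7955715276,6,0,0.7109914883
0.8362649019,10,0,1.602569302
0.4997420434,24,0,2.343510203
0.9999493894,1,1,-0.3252102102
0.9183855463,1.5,1,1.685428235
0.9133118018,2.5,1,1.657600447
0.7925873233,4,1,3.003566674
0.9063490364,6,1,-0.2107145998
0.729463936,10,1,1.167862973
0.8686310214,24,1,-0.1539294513
0.9587507527,1,1,2.039406494
0.9838454321,1.5,1,1.442080469
0.9727753078,2.5,1,1.07485771
0.9318670911,4,1,0.6930384134
0.8419744334,6,1,0.6749375804
0.7606280228,10,1,0.8615598911
0.6257483157,24,1,2.054934323
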