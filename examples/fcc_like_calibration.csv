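x,w
0.2,0.1874200329
0.4,0.3937390739
0.6,0.7546379526
0.8,0.6452291822
1,1.004474065
1.2,1.250122727
1.4,1.710943752
1.6,1.623724671
1.8,1.958280317
2,1.742850827
2.2,2.298636103
2.4,2.232379493
2.6,2.668088101
2.8,2.869012023
3,2.940125628
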