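run,mid,expected_percent,intra_run_replicate,observed_percent
1,1,100,1,100.0
1,2,90,1,96.4
1,3,75,1,87.7
1,9,50,1,85.3
1,4,50,2,60.2
1,7,50,3,64.3
1,5,25,1,35.6
1,10,25,2,38.7
1,8,10,1,24.9
1,6,0,1,0.2
2,7,100,1,99.7
2,3,90,1,94.8
2,8,75,1,91.8
2,9,50,1,84.5
2,10,50,2,61.5
2,6,50,3,74.5
2,1,25,1,29.8
2,4,25,2,28.2
2,5,10,1,15.7
2,2,0,1,0.6
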