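grouping,group,n,rr_success_pct,hr_success_pct
sedation,immobilized,18,88.9,72.2
sedation,voluntary,26,76.9,38.5
taxa,mammal,33,84.8,66.7
taxa,bird,6,50.0,33.3
taxa,reptile,5,100.0,0.0
integument,thick,21,66.7,38.1
integument,thin,23,95.7,69.6
quality,low,14,50.0,14.3
quality,high,30,96.7,74.3
fat,significant,10,60.0,40.0
fat,none,34,88.2,58.8
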