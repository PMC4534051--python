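agent_group	n_papers
P	21
T	19
P/T	5
B	2
B/V	1
Th	2
M	1
Cyt	1
P/F	2
P/S	1
T/G	1
P/F/L	2
P/F/I	2
Pr/V/M	1
P/C	1
P/F/I/L	1
R/Cyc/D/V/Pr	1
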