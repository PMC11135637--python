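1	|	1	|	no rank	|
2	|	1	|	superkingdom	|
3	|	13	|	genus	|
4	|	13	|	genus	|
5	|	3	|	species	|
6	|	3	|	species	|
7	|	4	|	species	|
9	|	5	|	strain	|
10	|	2	|	phylum	|
11	|	10	|	class	|
12	|	11	|	order	|
13	|	12	|	family	|
14	|	6	|	strain	|
15	|	7	|	strain	|
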