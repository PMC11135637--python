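1	|	root	|		|	scientific name	|
2	|	Bacteria	|		|	scientific name	|
3	|	Examplea	|		|	scientific name	|
4	|	Samplomonas	|		|	scientific name	|
5	|	Examplea prima	|		|	scientific name	|
6	|	Examplea secunda	|		|	scientific name	|
7	|	Samplomonas tertia	|		|	scientific name	|
9	|	Examplea prima str. A	|		|	scientific name	|
10	|	Demobacterota	|		|	scientific name	|
11	|	Demobacteria	|		|	scientific name	|
12	|	Demobacterales	|		|	scientific name	|
13	|	Demobacteraceae	|		|	scientific name	|
14	|	Examplea secunda str. B	|		|	scientific name	|
15	|	Samplomonas tertia str. C	|		|	scientific name	|
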