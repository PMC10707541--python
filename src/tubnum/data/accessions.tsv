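family	accession	flag
alpha	A0A5B9TE06	
alpha	A0A5B9T7A6	
alpha	A0A5B9T794	
alpha	A0A5B9T5X2	
alpha	A0A5B9T627	
alpha	A0A5B9TEC1	
alpha	Q65C79	
alpha	Q65C78	
alpha	A0A4U6STT5	
alpha	A0A4U6W1W4	
alpha	A0A4U6T6L3	
alpha	D5MRD7	
alpha	D5MRD8	
alpha	D5MRD9	
alpha	D5MRE0	
alpha	Q8WRT6	
alpha	P41351	
alpha	I7LY16	
alpha	Q23WP5	
alpha	Q22CD2	
alpha	P06603	
alpha	P06604	
alpha	P06605	
alpha	P06606	
alpha	Q9VED6	
alpha	O22347	
alpha	O22348	
alpha	O22349	
alpha	O18688	
alpha	P34690	
alpha	P91910	
alpha	G5EDD4	
alpha	Q19490	
alpha	P91873	
alpha	O18154	
alpha	P52274	
alpha	Q20221	
alpha	Q71U36	
alpha	P68363	
alpha	Q9BQE3	
alpha	P0DPH7	
alpha	P0DPH8	
alpha	Q6PEY2	
alpha	P68366	
alpha	Q9NY65	
alpha	A6NHL2	
alpha	O22661	
alpha	O22660	
alpha	A0A059T4F2	
alpha	A0A059T4U6	
alpha	A0A059T4Y0	
alpha	A0A059T4F4	
alpha	A0A059T464	
alpha	P11139	
alpha	B9DGT7	
alpha	Q56WH1	
alpha	Q0WV25	
alpha	B9DHQ0	
alpha	P29511	
alpha	P28752	
alpha	Q53M52	
alpha	P68362	
alpha	P68361	
alpha	P68365	
alpha	P09204	
alpha	P09205	
alpha	Q9DFR8	
alpha	Q9DD79	
alpha	Q9DFR7	
alpha	Q9DFR9	
alpha	Q78C10	
alpha	Q9YHW2	
alpha	Q9YHW1	
alpha	Q9DFT3	
alpha	Q7XYS1	
alpha	Q84KQ3	
alpha	A0A125YFV3	
alpha	P04688	
alpha	P04689	
alpha	P09733	
alpha	P09734	
alpha	P68369	
alpha	P05213	
alpha	P68373	
alpha	P05214	
alpha	P68368	
alpha	Q9JJZ2	
alpha	A0A125YQG0	
alpha	A0A125YTP7	
alpha	A0A125YQ52	
beta	A0A385HDR4	
beta	P12411	
beta	Q56YW9	
beta	Q9ASR0	
beta	P24636	
beta	P29513	
beta	P29514	
beta	P29515	
beta	P29516	
beta	P29517	
beta	O17921	
beta	P12456	
beta	P52275	
beta	P41937	
beta	G5EF01	
beta	Q18817	
beta	Q9DD57	
beta	P04690	
beta	P69893	
beta	A0A125YTB7	
beta	Q84KQ2	
beta	Q7XYS0	
beta	Q24560	
beta	P61857	
beta	P08841	
beta	Q9VAX7	
beta	Q9VRX3	
beta	Q9ZPP0	
beta	Q9ZPN9	
beta	Q9ZPN8	
beta	Q9ZPN7	
beta	Q9N2N6	
beta	C0L7F0	
beta	C0L7F2	
beta	C0L7F1	
beta	P07437	
beta	Q9H4B7	
beta	Q13885	
beta	Q9BVA1	
beta	Q13509	
beta	P04350	
beta	P68371	
beta	Q9BUF5	
beta	Q3ZCM7	
beta	A6NNZ2	
beta	A0A5B9T5X9	
beta	A0A5B9T5T1	
beta	A2AQ07	
beta	Q7TMM9	
beta	Q9CWF2	
beta	Q9ERD7	
beta	Q9D6F9	
beta	P68372	
beta	P99024	
beta	Q922F4	
beta	P36221	
beta	Q78C12	
beta	Q9DFT5	
beta	Q9DFT6	
beta	Q43594	
beta	Q8H7U1	
beta	Q40665	
beta	P45960	
beta	P46265	
beta	Q76FS3	
beta	P37832	
beta	Q76FS2	
beta	P02557	
beta	P05219	
beta	Q65C77	
beta	Q65C76	
beta	A0A4U6T2L9	
beta	A0A4V6D9T7	
beta	A0A4U6UB67	
beta	A0A4U6SU51	
beta	A0A4U6V2J9	
beta	A0A4U6WIH1	
beta	P41352	
beta	Q24D63	
beta	Q24D62	
beta	I6U4Q6	
beta	Q22ED2	
beta	A0A125YYZ6	
beta	A0A125YJU4	
beta	A0A125YWG5	
beta	P10653	
beta	P10874	
beta	A0A226BMV8	
beta	A0A226BIW8	
beta	E2RFJ7	
gamma	P38557	
gamma	P38558	
gamma	P34475	
gamma	Q39582	
gamma	G3HLY0	
gamma	P23257	
gamma	P42271	
gamma	A3F2R1	
gamma	P23258	
gamma	Q9NRH3	
gamma	P83887	
gamma	Q8VCK3	
gamma	O49068	
gamma	P53378	
gamma	P25295	
gamma	A0A4U6	truncated-ambiguous
gamma	O00849	
gamma	S8F111	
gamma	P18695	
gamma	O96769	
gamma	Q9TYH0	
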