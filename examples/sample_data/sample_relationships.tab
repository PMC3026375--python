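Sample ID	Sample name	Group	Recurrent Parent	Donor Parent	Replicate of	F1 ancestor
1	B73	Control				
2	B73	Control			1	
3	B73	Control			1	
4	Mo17	Control				
5	Mo17	Control			4	
6	Mo17	Control			4	
7	M0021	IBM	1	4		
8	B73xZ100	F1	1			
9	TIP Z	Inbred	1			8
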