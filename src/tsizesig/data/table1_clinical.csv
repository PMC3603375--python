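sample_id,stage,size_cm,grade,node,er,pgr,recurrence,deceased
24,T1,0.8,2,1,Positive,Positive,,
29,T1,0.8,2,0,Positive,Positive,,
51,T1,1.0,1,0,Positive,Negative,,
55,T1,0.8,3,0,Positive,Positive,,
62,T2,2.5,3,2,Negative,Negative,,
69,T1,1.4,2,0,Positive,Positive,,
73,T1,1.8,2,0,Positive,Positive,,
78,T1,1.2,2,0,Positive,Positive,,
81,T2,2.3,2,1,Positive,Positive,,
83,T1,1.9,3,1,Positive,Positive,,
84,T1,1.0,2,0,Positive,Positive,,
94,T1,1.9,3,0,Positive,Negative,Yes,Yes
99,T2,4.0,3,0,Negative,Negative,,
101,T1,1.9,3,0,Positive,Positive,,Yes
122,T2,3.4,3,1,Positive,Negative,,Yes
124,T1,0.9,1,0,Positive,Positive,,
129,T1,0.8,2,0,Positive,Negative,,
130,T2,2.2,3,2,Positive,Positive,Yes,Yes
143,T2,2.8,2,0,Positive,Positive,,
147,T1,1.0,1,0,Positive,Positive,,
148,T1,0.9,2,0,Positive,Positive,,
149,T1,1.0,1,0,Positive,Positive,,
152,T1,1.5,2,1,Positive,Positive,,
170,T2,4.0,2,1,Negative,Negative,,
172,T1,1.9,2,1,Negative,Negative,,Yes
175,T2,2.5,3,0,Negative,Negative,,
176,T2,2.7,3,0,Positive,Positive,,
178,T1,1.2,2,1,Negative,Positive,Yes,Yes
179,T1,1.8,2,1,Positive,Positive,,
191,T1,1.4,1,0,Positive,Positive,,
200,T1,1.5,2,0,Negative,Positive,,
211,T1,1.7,2,2,Positive,Positive,,
213,T2,3.0,3,1,Negative,Negative,,
214,T1,1.2,2,0,Positive,Negative,,
218,T2,2.1,1-2,1,Positive,Negative,,
222,T2,2.1,2,0,Positive,Positive,New BC,
227,T1,1.8,2,0,Negative,Positive,,
228,T2,3.0,3,0,Negative,Negative,,
231,T2,2.1,2,0,Positive,Negative,,
233,T2,3.0,3,0,Negative,Negative,New BC,
237,T2,2.1,2,0,Positive,Positive,,
244,T1,0.6,2,0,Positive,Positive,,
270,T2,3.0,3,0,Positive,Negative,Yes,
272,T2,2.3,2,1,Positive,Negative,,
280,T2,3.2,2,0,Negative,Positive,,
283,T1,1.3,2,1,Positive,Negative,,
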