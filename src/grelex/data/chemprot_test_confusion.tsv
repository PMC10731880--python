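pred\gold	False	CPR:3	CPR:4	CPR:5	CPR:6	CPR:9
False	12720	101	146	34	39	253
CPR:3	133	545	9	2	0	1
CPR:4	247	14	1497	0	1	5
CPR:5	50	3	0	159	0	1
CPR:6	72	0	3	0	253	0
CPR:9	253	2	6	0	0	384
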