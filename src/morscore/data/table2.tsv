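patient	hsa-let-7f-5p	hsa-let-7a-5p	hsa-miR-423-3p	hsa-miR-26a-5p	hsa-miR-144-3p	hsa-miR-451a	hsa-miR-215	hsa-miR-363-3p	mor_signal_score	delta_vas	dose_ratio	sae
#1	-2.7	-0.3	-1.0	0.2	-2.8	5.0	-5.6	-3.5	3.0	4.3	1:5
#2	-1.7	0.9	-1.3	0.4	-2.0	5.4	-5.0	-2.9	2.7	4.3	1:8
#3	-2.0	0.3	-0.9	0.1	-1.9	5.7	-5.1	-3.5	2.2	2.7	1:5
#4	-2.3	0.2	-1.3	-0.3	-2.1	5.2	-5.1	-3.3	1.6	-1.0	1:8
#5	-2.5	-0.1	-1.3	0.2	-2.0	5.8	-4.7	-3.2	0.5	1.7	1:8
#6	-2.0	0.2	-0.9	0.0	-1.6	5.7	-4.1	-2.4	-0.2	1.7	1:8
#7	-1.9	0.4	-1.3	0.2	-1.6	5.9	-2.7	-3.3	-0.9	6.0	1:8
#8	-2.1	0.1	-1.1	0.3	-0.6	6.3	-4.4	-2.8	-1.2	6.7	1:5
#9	-1.3	0.5	-1.8	0.1	-1.3	6.6	-3.6	-2.4	-1.9	NA	1:8	+
#10	-2.5	0.0	-1.2	-0.2	-1.3	5.8	-3.1	-2.8	-2.4	1.0	1:5
#11	-2.1	0.5	-1.9	0.2	-0.4	6.5	-4.1	-2.7	-2.7	2.3	1:5	+
#12	-2.3	0.1	-1.5	-0.4	-1.0	6.2	-4.0	-2.5	-2.9	9.4	1:5	+
#13	-1.9	-0.2	-1.8	-0.2	-0.5	7.0	-5.1	-2.5	-3.0	0.7	1:5
#14	-1.5	1.0	-1.7	-0.1	-0.1	6.8	-2.4	-3.1	-3.3	2.7	1:8
#15	-1.9	0.8	-2.2	-0.4	0.0	7.0	-4.9	-2.4	-3.4	0.3	1:8
#16	-2.6	0.0	-2.1	-0.4	-1.2	6.1	-4.0	-2.5	-3.4	0.0	1:8
#17	-3.1	0.0	-1.1	-0.2	-1.5	5.7	-0.9	-3.1	-4.7	NA	1:5	+
#18	-2.5	-0.1	-1.4	-0.3	-0.6	6.4	-3.6	-1.6	-4.9	-13.0	1:8
#19	-2.5	0.1	-1.9	-0.5	0.0	6.2	-3.3	-2.2	-5.4	-1.3	1:5
#20	-2.6	0.2	-2.2	-0.5	0.1	7.5	-3.4	-2.1	-7.2	-0.3	1:8
#21	-2.7	-0.3	-1.5	-0.6	0.2	7.4	-3.5	-1.8	-7.6	7.3	1:5
#22	-2.7	0.7	-2.4	-0.7	-0.1	7.6	-2.1	-1.6	-8.8	-2.0	1:8
#23	-2.5	0.1	-2.5	-1.2	0.4	7.4	-3.4	-1.1	-9.4	0.0	1:8
#24	-3.8	-0.1	-3.6	-1.7	-0.4	7.2	-3.9	-2.5	-9.7	0.0	1:5
#25	-3.8	-1.2	-2.4	-3.2	1.5	8.2	-3.3	-0.6	-16.4	-1.7	1:5
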