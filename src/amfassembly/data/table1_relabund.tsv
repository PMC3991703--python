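sample_id	Glo-1	Glo-2	Glo-3	Glo-4	Glo-5	Glo-6	Glo-7	Glo-8	Glo-9	Glo-10	Glo-11	Glo-12	Glo-13	Glo-14	Aca-15	Aca-16	Aca-17	Aca-18	Ent-19	Pac-20	Scu-21	Div-22	Cla-23	Cla-24	Cla-25	Cla-26	Arc-27	Amb-28	Geo-29	Par-30
Lv-LD	0	6.7	5.2	9.0	0	3.7	0	9.0	7.5	0	21.6	9.7	1.5	0	3.0	0	0	0	0	0	0	3.0	9.0	2.2	8.2	0.7	0	0	0	0
Lv-MD	0	10.1	0	2.5	0	1.9	0	1.9	52.8	1.3	0	1.9	0	0	0	0	0	2.5	0	0	0	0.6	5.0	0	9.4	8.8	0	0	0	1.3
Lv-HD	4.9	7.0	9.8	0	1.4	0	0	5.6	0.7	0	0	0	5.6	30.1	0	0	0	0	0.7	1.4	3.5	9.1	4.2	0	0	0	11.2	4.9	0	0
Nb-Control	0	13.6	0	1.1	0	3.4	0	14.1	11.9	0	0	13.6	0.6	2.3	3.4	0	0	0	0	0	0	7.3	5.1	0	7.3	0	0	16.4	0	0
Nb-LD	0	16.7	3.0	14.3	0	3.4	2.0	1.0	12.8	1.5	10.3	20.2	0	1.5	0	0	0	0	0	0	0	0	0	0	13.3	0	0	0	0	0
Nb-MD	0	26.8	0.6	6.7	0	1.7	0	5.0	24.0	0.6	3.4	10.1	0	2.2	0	0	0	0	0	0	0	0.6	3.9	0	12.3	0	1.7	0.6	0	0
Nb-HD	5.4	37.0	0	0	0	0	6.0	10.9	0	8.7	0	4.9	2.2	1.6	1.1	0.5	0.5	3.8	0	0	0	6.0	3.3	0	6.5	0	0	1.1	0.5	0
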