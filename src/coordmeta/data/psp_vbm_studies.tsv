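study_id	n_patients	male_patients	n_controls	male_controls	age_patient_mean	age_patient_sd	age_control_mean	age_control_sd	updrs3_mean	updrs3_sd	hy_mean	hy_sd	duration_mean	duration_sd	mmse_mean	mmse_sd	fab_mean	fab_sd	scanner_tesla	software	smoothing_fwhm_mm	threshold_p	threshold_corrected	quality_score	subgroup_tags
Brenneis2004	12	NA	12	NA	67.5	6.6	60	5.8	38.9	10.9	NA	NA	2.7	0.9	NA	NA	NA	NA	1.5	SPM99	10	0.05	true	8.5	PSP-RS-criteria
Price2004	12	7	12	8	65.3	5.8	67.4	4.6	20.4	8.7	NA	NA	4.8	1.7	27	3.3	12.4	3.1	1.5	SPM99	8	0.05	true	9.5	PSP-RS-criteria
Cordato2005	21	14	23	14	70.3	6.4	71.5	7.2	23.1	10.1	3.8	1.1	4	2.8	25.4	3.2	NA	NA	1.5	SPM99	12	0.05	true	9.5	PSP-RS-criteria
Boxer2006	15	9	80	37	70.9	6.9	67.9	8.6	NA	NA	3.3	0.5	4.8	1.7	24	3.2	NA	NA	1.5	SPM2	12	0.05	true	8.5	PSP-RS-criteria
Padovani2006	14	7	14	7	73	5.6	65.6	4.1	22.1	8.9	NA	NA	3.1	1	25.8	2.7	NA	NA	1.5	SPM2	10	0.005	true	9	NA
Agosta2010	20	14	24	13	64.9	NA	63.8	NA	32.8	NA	3	NA	4.5	NA	27	NA	NA	NA	1.5	SPM5	8	0.001	false	9	PSP-RS-criteria
Lehericy2010	10	6	9	5	66.9	6.4	66.5	4.8	30	NA	NA	NA	4.3	1	27	NA	11.5	NA	1.5	SPM5	8	0.05	true	8.5	PSP-RS-criteria
Takahashi2011	16	11	20	16	64.6	6.4	64.8	6.4	NA	NA	NA	NA	NA	NA	21	4.4	NA	NA	1.5	SPM8	8	0.001	false	8.5	PSP-RS-criteria
Ghosh2012	23	14	22	15	71.1	8.6	71.4	7.6	33.8	15.7	NA	NA	2.5	NA	NA	NA	NA	NA	3	SPM5	NA	0.05	true	9	PSP-RS-criteria
Giordano2013	15	8	15	8	68.91	1.2	65.5	6.1	38.33	4	3.8	1.1	3.16	1.3	21.23	1.2	7.81	0.9	3	SPM8	8	0.05	true	9.5	PSP-RS-criteria
Kamiya2013	16	10	21	12	71.4	6	70.9	8	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	1.5	SPM5	8	0.001	false	9	PSP-RS-criteria
Lagarde2013	19	7	18	7	65.9	6.5	67.8	5.2	NA	NA	NA	NA	4.5	1.8	25.5	2.7	11.3	2	3	SPM8	8	0.05	true	9	PSP-RS-criteria
Whitwell2013	16	8	20	4	72.1	4.6	73.9	6.3	52.9	12.6	NA	NA	4	1.1	25.8	2.7	12.9	2.2	3	SPM5	8	0.05	true	9	PSP-RS-criteria
Sandhya2014	10	9	8	5	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	3	SPM8	NA	0.001	false	8	NA
Burciu2015	20	10	20	10	67.8	7.1	64.8	8.8	39	14.5	2.6	0.9	2.6	2.6	NA	NA	NA	NA	3	SPM8	NA	0.05	true	9	PSP-RS-criteria
Piattella2015	16	9	16	6	68.08	5.9	69.4	0.4	27	17.4	2.9	1	3.1	NA	24.3	3.9	11.1	3.8	3	SPM8	12	0.05	true	9.5	NA
Wang2015	24	8	23	14	64.17	6.72	60.52	6.47	NA	NA	3.1	NA	3.87	2.62	23.54	4.28	NA	NA	3	SPM8	6	0.001	true	8.5	PSP-RS-criteria
SantosSantos2016	5	1	10	3	71.5	NA	74	NA	NA	NA	NA	NA	4	NA	28	NA	NA	NA	NA	SPM12	NA	0.001	false	8	NA
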