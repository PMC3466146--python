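genome_id	subphylum	taa_f1	tag_f1	tga_f1	taa_f2	tag_f2	tga_f2	taa_f3	tag_f3	tga_f3
Orientia tsutsugamushi Boryong	alpha	0.010	0.003	0.003	0.186	0.157	0.063	0.281	0.102	0.195
Rickettsia akari str. Hartford	alpha	0.009	0.004	0.005	0.200	0.164	0.061	0.277	0.088	0.192
Rickettsia bellii OSU 85-389	alpha	0.009	0.003	0.003	0.198	0.163	0.053	0.285	0.086	0.200
Rickettsia bellii RML369-C	alpha	0.009	0.003	0.002	0.198	0.164	0.053	0.286	0.086	0.199
Rickettsia canadensis str. McKi	alpha	0.010	0.003	0.003	0.205	0.163	0.057	0.280	0.090	0.189
Rickettsia conorii Malish 7	alpha	0.010	0.004	0.003	0.206	0.165	0.058	0.279	0.089	0.185
Rickettsia felis URRWXCal2	alpha	0.008	0.004	0.003	0.204	0.167	0.054	0.283	0.088	0.189
Rickettsia massiliae MTU5	alpha	0.008	0.003	0.002	0.206	0.166	0.056	0.281	0.091	0.186
Rickettsia prowazekii str. Madrid E	alpha	0.009	0.002	0.002	0.204	0.163	0.059	0.283	0.086	0.193
Rickettsia rickettsii str. Iowa	alpha	0.011	0.004	0.004	0.205	0.165	0.059	0.279	0.088	0.185
Rickettsia rickettsii str. Shei	alpha	0.010	0.004	0.004	0.204	0.167	0.058	0.279	0.089	0.186
Rickettsia typhi str. Wilmington	alpha	0.008	0.002	0.002	0.202	0.161	0.059	0.284	0.086	0.195
Wolbachia pipientis Drosophila (wBm)	alpha	0.016	0.009	0.008	0.198	0.153	0.098	0.209	0.082	0.228
Wolbachia pipientis Brugia (wMel)	alpha	0.011	0.006	0.005	0.201	0.158	0.095	0.216	0.085	0.223
Neisseria flavescens SK114	beta	0.027	0.004	0.010	0.078	0.074	0.329	0.176	0.025	0.278
Neisseria gonorrhoeae FA1090	beta	0.026	0.006	0.020	0.098	0.066	0.402	0.141	0.021	0.222
Neisseria meningitidis 053442	beta	0.024	0.006	0.018	0.095	0.069	0.380	0.152	0.024	0.232
Neisseria meningitidis FAM18	beta	0.023	0.005	0.019	0.096	0.072	0.381	0.152	0.025	0.227
Neisseria meningitidis MC58	beta	0.024	0.006	0.018	0.097	0.073	0.372	0.157	0.026	0.227
Neisseria meningitidis Z2491	beta	0.025	0.006	0.019	0.097	0.070	0.383	0.152	0.024	0.225
Escherichia coli W3110	gamma	0.020	0.003	0.012	0.091	0.064	0.274	0.205	0.040	0.291
Escherichia coli 536	gamma	0.018	0.002	0.009	0.092	0.066	0.272	0.207	0.040	0.296
Escherichia coli 55989	gamma	0.017	0.002	0.009	0.089	0.060	0.269	0.209	0.039	0.305
Escherichia coli APEC O1	gamma	0.017	0.002	0.008	0.092	0.064	0.270	0.209	0.039	0.301
Escherichia coli ATCC 8739	gamma	0.018	0.002	0.008	0.091	0.065	0.275	0.206	0.040	0.295
Escherichia coli B str. REL606	gamma	0.018	0.002	0.008	0.090	0.064	0.277	0.207	0.039	0.295
Escherichia coli BL21(DE3)	gamma	0.019	0.002	0.008	0.089	0.064	0.278	0.206	0.039	0.295
Escherichia coli BW2952	gamma	0.018	0.002	0.009	0.091	0.064	0.272	0.207	0.039	0.299
Escherichia coli CFT073	gamma	0.019	0.003	0.012	0.095	0.064	0.271	0.205	0.040	0.291
Escherichia coli E24377A	gamma	0.018	0.002	0.009	0.091	0.063	0.272	0.207	0.039	0.298
Escherichia coli ED1a	gamma	0.018	0.002	0.010	0.090	0.062	0.277	0.205	0.037	0.301
Escherichia coli IAI1	gamma	0.018	0.002	0.008	0.090	0.064	0.273	0.208	0.040	0.296
Escherichia coli IAI39	gamma	0.018	0.002	0.009	0.092	0.062	0.272	0.209	0.038	0.297
Escherichia coli O127-H6 str- E2348_69	gamma	0.018	0.002	0.008	0.088	0.064	0.279	0.205	0.039	0.295
Escherichia coli O157:H7 EDL933	gamma	0.017	0.002	0.010	0.093	0.062	0.267	0.209	0.040	0.300
Escherichia coli O157:H7 str. Sakai	gamma	0.017	0.002	0.010	0.093	0.062	0.268	0.208	0.039	0.300
Escherichia coli O157-H7 str- Ec4115	gamma	0.018	0.003	0.010	0.092	0.062	0.268	0.209	0.039	0.301
Escherichia coli S88	gamma	0.018	0.002	0.009	0.090	0.064	0.275	0.206	0.038	0.299
Escherichia coli SE11	gamma	0.018	0.002	0.009	0.091	0.063	0.273	0.207	0.039	0.298
Escherichia coli SMS-3-5	gamma	0.018	0.002	0.009	0.093	0.064	0.270	0.210	0.039	0.295
Escherichia coli str. K-12 MG1655	gamma	0.018	0.002	0.008	0.090	0.064	0.277	0.207	0.040	0.293
Escherichia coli UMN026	gamma	0.017	0.002	0.009	0.093	0.064	0.272	0.208	0.039	0.296
Escherichia coli UTI89	gamma	0.018	0.002	0.009	0.093	0.065	0.272	0.206	0.040	0.295
Escherichia fergusonii ATCC 35469	gamma	0.017	0.002	0.008	0.094	0.067	0.258	0.207	0.041	0.305
Salmonella typhi Ty2	gamma	0.018	0.003	0.010	0.091	0.068	0.273	0.217	0.045	0.275
Salmonella choleraesuis str. SC-B67	gamma	0.020	0.004	0.013	0.094	0.069	0.270	0.216	0.045	0.269
Salmonella paratyphi A str. ATCC 9150	gamma	0.018	0.003	0.009	0.091	0.069	0.272	0.219	0.046	0.272
Salmonella typhi str. CT18	gamma	0.018	0.003	0.010	0.091	0.068	0.272	0.217	0.045	0.276
Salmonella typhimurium str. LT2	gamma	0.018	0.003	0.009	0.092	0.068	0.272	0.219	0.045	0.274
Shigella boydii Sb227	gamma	0.021	0.004	0.014	0.088	0.060	0.280	0.201	0.036	0.297
Shigella dysenteriae Sd197	gamma	0.024	0.004	0.013	0.084	0.062	0.279	0.203	0.038	0.294
Shigella flexneri 2a str. 301	gamma	0.019	0.002	0.008	0.090	0.063	0.279	0.204	0.037	0.297
Shigella sonnei Ss046	gamma	0.020	0.003	0.011	0.088	0.061	0.283	0.202	0.035	0.297
Yersinia enterocolitica 8081	gamma	0.014	0.003	0.006	0.088	0.096	0.219	0.209	0.048	0.316
Yersinia pestis Angola	gamma	0.015	0.004	0.007	0.087	0.094	0.223	0.213	0.045	0.312
Yersinia pestis Antiqua JGI	gamma	0.014	0.003	0.007	0.088	0.094	0.223	0.213	0.046	0.312
Yersinia pestis biovar Medieval 91001	gamma	0.013	0.004	0.007	0.090	0.093	0.225	0.211	0.046	0.311
Yersinia pestis CO92	gamma	0.013	0.003	0.007	0.088	0.094	0.224	0.212	0.046	0.312
Yersinia pestis KIM	gamma	0.014	0.004	0.007	0.090	0.094	0.224	0.211	0.047	0.309
Yersinia pseudotuberculosis IP 31758	gamma	0.013	0.004	0.007	0.088	0.094	0.221	0.214	0.047	0.313
Yersinia pseudotuberculosis IP 32953	gamma	0.013	0.003	0.007	0.088	0.094	0.221	0.214	0.047	0.314
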