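# synthetic parcellation label table: 180 areas + 1 unassigned per hemisphere
area	hemisphere
L_A001	L
L_A002	L
L_A003	L
L_A004	L
L_A005	L
L_A006	L
L_A007	L
L_A008	L
L_A009	L
L_A010	L
L_A011	L
L_A012	L
L_A013	L
L_A014	L
L_A015	L
L_A016	L
L_A017	L
L_A018	L
L_A019	L
L_A020	L
L_A021	L
L_A022	L
L_A023	L
L_A024	L
L_A025	L
L_A026	L
L_A027	L
L_A028	L
L_A029	L
L_A030	L
L_A031	L
L_A032	L
L_A033	L
L_A034	L
L_A035	L
L_A036	L
L_A037	L
L_A038	L
L_A039	L
L_A040	L
L_A041	L
L_A042	L
L_A043	L
L_A044	L
L_A045	L
L_A046	L
L_A047	L
L_A048	L
L_A049	L
L_A050	L
L_A051	L
L_A052	L
L_A053	L
L_A054	L
L_A055	L
L_A056	L
L_A057	L
L_A058	L
L_A059	L
L_A060	L
L_A061	L
L_A062	L
L_A063	L
L_A064	L
L_A065	L
L_A066	L
L_A067	L
L_A068	L
L_A069	L
L_A070	L
L_A071	L
L_A072	L
L_A073	L
L_A074	L
L_A075	L
L_A076	L
L_A077	L
L_A078	L
L_A079	L
L_A080	L
L_A081	L
L_A082	L
L_A083	L
L_A084	L
L_A085	L
L_A086	L
L_A087	L
L_A088	L
L_A089	L
L_A090	L
L_A091	L
L_A092	L
L_A093	L
L_A094	L
L_A095	L
L_A096	L
L_A097	L
L_A098	L
L_A099	L
L_A100	L
L_A101	L
L_A102	L
L_A103	L
L_A104	L
L_A105	L
L_A106	L
L_A107	L
L_A108	L
L_A109	L
L_A110	L
L_A111	L
L_A112	L
L_A113	L
L_A114	L
L_A115	L
L_A116	L
L_A117	L
L_A118	L
L_A119	L
L_A120	L
L_A121	L
L_A122	L
L_A123	L
L_A124	L
L_A125	L
L_A126	L
L_A127	L
L_A128	L
L_A129	L
L_A130	L
L_A131	L
L_A132	L
L_A133	L
L_A134	L
L_A135	L
L_A136	L
L_A137	L
L_A138	L
L_A139	L
L_A140	L
L_A141	L
L_A142	L
L_A143	L
L_A144	L
L_A145	L
L_A146	L
L_A147	L
L_A148	L
L_A149	L
L_A150	L
L_A151	L
L_A152	L
L_A153	L
L_A154	L
L_A155	L
L_A156	L
L_A157	L
L_A158	L
L_A159	L
L_A160	L
L_A161	L
L_A162	L
L_A163	L
L_A164	L
L_A165	L
L_A166	L
L_A167	L
L_A168	L
L_A169	L
L_A170	L
L_A171	L
L_A172	L
L_A173	L
L_A174	L
L_A175	L
L_A176	L
L_A177	L
L_A178	L
L_A179	L
L_A180	L
L_unassigned	L
R_A001	R
R_A002	R
R_A003	R
R_A004	R
R_A005	R
R_A006	R
R_A007	R
R_A008	R
R_A009	R
R_A010	R
R_A011	R
R_A012	R
R_A013	R
R_A014	R
R_A015	R
R_A016	R
R_A017	R
R_A018	R
R_A019	R
R_A020	R
R_A021	R
R_A022	R
R_A023	R
R_A024	R
R_A025	R
R_A026	R
R_A027	R
R_A028	R
R_A029	R
R_A030	R
R_A031	R
R_A032	R
R_A033	R
R_A034	R
R_A035	R
R_A036	R
R_A037	R
R_A038	R
R_A039	R
R_A040	R
R_A041	R
R_A042	R
R_A043	R
R_A044	R
R_A045	R
R_A046	R
R_A047	R
R_A048	R
R_A049	R
R_A050	R
R_A051	R
R_A052	R
R_A053	R
R_A054	R
R_A055	R
R_A056	R
R_A057	R
R_A058	R
R_A059	R
R_A060	R
R_A061	R
R_A062	R
R_A063	R
R_A064	R
R_A065	R
R_A066	R
R_A067	R
R_A068	R
R_A069	R
R_A070	R
R_A071	R
R_A072	R
R_A073	R
R_A074	R
R_A075	R
R_A076	R
R_A077	R
R_A078	R
R_A079	R
R_A080	R
R_A081	R
R_A082	R
R_A083	R
R_A084	R
R_A085	R
R_A086	R
R_A087	R
R_A088	R
R_A089	R
R_A090	R
R_A091	R
R_A092	R
R_A093	R
R_A094	R
R_A095	R
R_A096	R
R_A097	R
R_A098	R
R_A099	R
R_A100	R
R_A101	R
R_A102	R
R_A103	R
R_A104	R
R_A105	R
R_A106	R
R_A107	R
R_A108	R
R_A109	R
R_A110	R
R_A111	R
R_A112	R
R_A113	R
R_A114	R
R_A115	R
R_A116	R
R_A117	R
R_A118	R
R_A119	R
R_A120	R
R_A121	R
R_A122	R
R_A123	R
R_A124	R
R_A125	R
R_A126	R
R_A127	R
R_A128	R
R_A129	R
R_A130	R
R_A131	R
R_A132	R
R_A133	R
R_A134	R
R_A135	R
R_A136	R
R_A137	R
R_A138	R
R_A139	R
R_A140	R
R_A141	R
R_A142	R
R_A143	R
R_A144	R
R_A145	R
R_A146	R
R_A147	R
R_A148	R
R_A149	R
R_A150	R
R_A151	R
R_A152	R
R_A153	R
R_A154	R
R_A155	R
R_A156	R
R_A157	R
R_A158	R
R_A159	R
R_A160	R
R_A161	R
R_A162	R
R_A163	R
R_A164	R
R_A165	R
R_A166	R
R_A167	R
R_A168	R
R_A169	R
R_A170	R
R_A171	R
R_A172	R
R_A173	R
R_A174	R
R_A175	R
R_A176	R
R_A177	R
R_A178	R
R_A179	R
R_A180	R
R_unassigned	R
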