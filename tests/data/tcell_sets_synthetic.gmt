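Tfh_cells	synthetic stand-in T-cell subset list	TRG001	TRG002	TRG003	TRG004	TRG005	TRG006	TRG007	TRG008	TRG009	TRG010	TRG011	TRG012	TRG013	TRG014	TRG015	TRG016	TRG017	TRG018	TRG019	TRG020	TRG021	TRG022	TRG023	TRG024	TRG025	TRG026	TRG027	TRG028	TRG029	TRG030	TRG031	TRG032	TRG033	TRG034	TRG035	TRG036
Th1_cells	synthetic stand-in T-cell subset list	TRG037	TRG038	TRG039	TRG040	TRG041	TRG042	TRG043	TRG044	TRG045	TRG046	TRG047	TRG048	TRG049	TRG050	TRG051	TRG052	TRG053	TRG054	TRG055	TRG056	TRG057	TRG058	TRG059	TRG060	TRG061	TRG062	TRG063	TRG064	TRG065	TRG066	TRG067	TRG068	TRG069	TRG070	TRG071	TRG072	TRG073	TRG074	TRG075	TRG076	TRG077	TRG078	TRG079	TRG080	TRG081	TRG082	TRG083	TRG084	TRG085	TRG086	TRG087	TRG088	TRG089	TRG090	TRG091	TRG092	TRG093	TRG094	TRG095	TRG096	TRG097	TRG098	TRG099	TRG100	TRG101	TRG102	TRG103	TRG104	TRG105	TRG106	TRG107	TRG108	TRG109	TRG110	TRG111	TRG112	TRG113
Th17_cells	synthetic stand-in T-cell subset list	TRG114	TRG115	TRG116	TRG117	TRG118	TRG119	TRG120	TRG121	TRG122	TRG123	TRG124	TRG125	TRG126	TRG127	TRG128	TRG129	TRG130	TRG131	TRG132	TRG133	TRG134	TRG135	TRG136	TRG137	TRG138	TRG139	TRG140
Th2_cells	synthetic stand-in T-cell subset list	TRG141	TRG142	TRG143	TRG144	TRG145	TRG146	TRG147	TRG148	TRG149	TRG150	TRG151	TRG152	TRG153	TRG154	TRG155	TRG156	TRG157	TRG158	TRG159	TRG160	TRG161	TRG162	TRG163	TRG164	TRG165	TRG166	TRG167	TRG168	TRG169
Treg_cells	synthetic stand-in T-cell subset list	TRG170	TRG171	TRG172	TRG173	TRG174	TRG175	TRG176	TRG177	TRG178	TRG179	TRG180	TRG181	TRG182	TRG183	TRG184	TRG185	TRG186	TRG187	TRG188	TRG189
NKT_cells	synthetic stand-in T-cell subset list	TRG190	TRG191	TRG192	TRG193	TRG194	TRG195	TRG196	TRG197	TRG198	TRG199	TRG200	TRG201	TRG202	TRG203	TRG204	TRG205	TRG206	TRG207	TRG208	TRG209	TRG210	TRG211	TRG212	TRG213	TRG214	TRG215	TRG216	TRG217	TRG218	TRG219	TRG220	TRG221	TRG222	TRG223	TRG224	TRG225	TRG226	TRG227	TRG228	TRG229	TRG230	TRG231	TRG232	TRG233	TRG001	TRG002	TRG003	TRG004	TRG005	TRG006	TRG007	TRG008	TRG009	TRG010	TRG011	TRG012	TRG013	TRG014	TRG015	TRG016	TRG017	TRG018	TRG019	TRG020
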