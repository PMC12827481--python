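ATF3	synthetic stand-in regulon members	SYNT0001	SYNT0002	SYNT0003	SYNT0004	SYNT0005	SYNT0006	SYNT0007	SYNT0008	SYNT0009	SYNT0010	SYNT0011	SYNT0012	SYNT0013	SYNT0014	SYNT0015	SYNT0016	SYNT0017	SYNT0018	SYNT0019	SYNT0020	SYNT0021	SYNT0022	SYNT0023	SYNT0024	SYNT0025	SYNT0026	SYNT0027	SYNT0028	SYNT0029	SYNT0030	SYNT0031	SYNT0032	SYNT0033	SYNT0034	SYNT0035
E2F3	synthetic stand-in regulon members	SYNT0036	SYNT0037	SYNT0038	SYNT0039	SYNT0040	SYNT0041	SYNT0042	SYNT0043	SYNT0044	SYNT0045	SYNT0046	SYNT0047	SYNT0048	SYNT0049	SYNT0050	SYNT0051	SYNT0052	SYNT0053	SYNT0054	SYNT0055	SYNT0056	SYNT0057	SYNT0058	SYNT0059	SYNT0060	SYNT0061	SYNT0062	SYNT0063
FOXA1	synthetic stand-in regulon members	SYNT0064	SYNT0065	SYNT0066	SYNT0067	SYNT0068	SYNT0069	SYNT0070	SYNT0071	SYNT0072	SYNT0073	SYNT0074	SYNT0075	SYNT0076	SYNT0077	SYNT0078	SYNT0079	SYNT0080	SYNT0081	SYNT0082	SYNT0083	SYNT0084	SYNT0085	SYNT0086	SYNT0087	SYNT0088	SYNT0089	SYNT0090	SYNT0091	SYNT0092	SYNT0093
FOXO3	synthetic stand-in regulon members	SYNT0094	SYNT0095	SYNT0096	SYNT0097	SYNT0098	SYNT0099	SYNT0100	SYNT0101	SYNT0102	SYNT0103	SYNT0104	SYNT0105	SYNT0106	SYNT0107	SYNT0108	SYNT0109	SYNT0110	SYNT0111	SYNT0112	SYNT0113	SYNT0114	SYNT0115	SYNT0116	SYNT0117	SYNT0118	SYNT0119	SYNT0120	SYNT0121	SYNT0122	SYNT0123	SYNT0124	SYNT0125
JUN	synthetic stand-in regulon members	SYNT0126	SYNT0127	SYNT0128	SYNT0129	SYNT0130	SYNT0131	SYNT0132	SYNT0133	SYNT0134	SYNT0135	SYNT0136	SYNT0137	SYNT0138	SYNT0139	SYNT0140	SYNT0141	SYNT0142	SYNT0143	SYNT0144	SYNT0145	SYNT0146	SYNT0147	SYNT0148	SYNT0149	SYNT0150	SYNT0151	SYNT0152	SYNT0153	SYNT0154	SYNT0155	SYNT0156	SYNT0157	SYNT0158	SYNT0159	SYNT0160	SYNT0161	SYNT0162	SYNT0163	SYNT0164	SYNT0165	SYNT0166	SYNT0167	SYNT0168	SYNT0169	SYNT0170	SYNT0171	SYNT0172	SYNT0173	SYNT0174	SYNT0175	SYNT0176	SYNT0177	SYNT0178
PPARG	synthetic stand-in regulon members	SYNT0179	SYNT0180	SYNT0181	SYNT0182	SYNT0183	SYNT0184	SYNT0185	SYNT0186	SYNT0187	SYNT0188	SYNT0189	SYNT0190	SYNT0191	SYNT0192	SYNT0193	SYNT0194	SYNT0195	SYNT0196	SYNT0197	SYNT0198	SYNT0199	SYNT0200	SYNT0201	SYNT0202	SYNT0203
REST	synthetic stand-in regulon members	SYNT0204	SYNT0205	SYNT0206	SYNT0207	SYNT0208	SYNT0209	SYNT0210	SYNT0211	SYNT0212	SYNT0213	SYNT0214	SYNT0215	SYNT0216	SYNT0217	SYNT0218	SYNT0219	SYNT0220	SYNT0221	SYNT0222	SYNT0223
TFAP4	synthetic stand-in regulon members	SYNT0224	SYNT0225	SYNT0226	SYNT0227	SYNT0228	SYNT0229	SYNT0230	SYNT0231	SYNT0232	SYNT0233	SYNT0234	SYNT0235	SYNT0236	SYNT0237	SYNT0238	SYNT0239	SYNT0240	SYNT0241
AEGIS_combined	synthetic stand-in combined signature (241 genes)	SYNT0001	SYNT0002	SYNT0003	SYNT0004	SYNT0005	SYNT0006	SYNT0007	SYNT0008	SYNT0009	SYNT0010	SYNT0011	SYNT0012	SYNT0013	SYNT0014	SYNT0015	SYNT0016	SYNT0017	SYNT0018	SYNT0019	SYNT0020	SYNT0021	SYNT0022	SYNT0023	SYNT0024	SYNT0025	SYNT0026	SYNT0027	SYNT0028	SYNT0029	SYNT0030	SYNT0031	SYNT0032	SYNT0033	SYNT0034	SYNT0035	SYNT0036	SYNT0037	SYNT0038	SYNT0039	SYNT0040	SYNT0041	SYNT0042	SYNT0043	SYNT0044	SYNT0045	SYNT0046	SYNT0047	SYNT0048	SYNT0049	SYNT0050	SYNT0051	SYNT0052	SYNT0053	SYNT0054	SYNT0055	SYNT0056	SYNT0057	SYNT0058	SYNT0059	SYNT0060	SYNT0061	SYNT0062	SYNT0063	SYNT0064	SYNT0065	SYNT0066	SYNT0067	SYNT0068	SYNT0069	SYNT0070	SYNT0071	SYNT0072	SYNT0073	SYNT0074	SYNT0075	SYNT0076	SYNT0077	SYNT0078	SYNT0079	SYNT0080	SYNT0081	SYNT0082	SYNT0083	SYNT0084	SYNT0085	SYNT0086	SYNT0087	SYNT0088	SYNT0089	SYNT0090	SYNT0091	SYNT0092	SYNT0093	SYNT0094	SYNT0095	SYNT0096	SYNT0097	SYNT0098	SYNT0099	SYNT0100	SYNT0101	SYNT0102	SYNT0103	SYNT0104	SYNT0105	SYNT0106	SYNT0107	SYNT0108	SYNT0109	SYNT0110	SYNT0111	SYNT0112	SYNT0113	SYNT0114	SYNT0115	SYNT0116	SYNT0117	SYNT0118	SYNT0119	SYNT0120	SYNT0121	SYNT0122	SYNT0123	SYNT0124	SYNT0125	SYNT0126	SYNT0127	SYNT0128	SYNT0129	SYNT0130	SYNT0131	SYNT0132	SYNT0133	SYNT0134	SYNT0135	SYNT0136	SYNT0137	SYNT0138	SYNT0139	SYNT0140	SYNT0141	SYNT0142	SYNT0143	SYNT0144	SYNT0145	SYNT0146	SYNT0147	SYNT0148	SYNT0149	SYNT0150	SYNT0151	SYNT0152	SYNT0153	SYNT0154	SYNT0155	SYNT0156	SYNT0157	SYNT0158	SYNT0159	SYNT0160	SYNT0161	SYNT0162	SYNT0163	SYNT0164	SYNT0165	SYNT0166	SYNT0167	SYNT0168	SYNT0169	SYNT0170	SYNT0171	SYNT0172	SYNT0173	SYNT0174	SYNT0175	SYNT0176	SYNT0177	SYNT0178	SYNT0179	SYNT0180	SYNT0181	SYNT0182	SYNT0183	SYNT0184	SYNT0185	SYNT0186	SYNT0187	SYNT0188	SYNT0189	SYNT0190	SYNT0191	SYNT0192	SYNT0193	SYNT0194	SYNT0195	SYNT0196	SYNT0197	SYNT0198	SYNT0199	SYNT0200	SYNT0201	SYNT0202	SYNT0203	SYNT0204	SYNT0205	SYNT0206	SYNT0207	SYNT0208	SYNT0209	SYNT0210	SYNT0211	SYNT0212	SYNT0213	SYNT0214	SYNT0215	SYNT0216	SYNT0217	SYNT0218	SYNT0219	SYNT0220	SYNT0221	SYNT0222	SYNT0223	SYNT0224	SYNT0225	SYNT0226	SYNT0227	SYNT0228	SYNT0229	SYNT0230	SYNT0231	SYNT0232	SYNT0233	SYNT0234	SYNT0235	SYNT0236	SYNT0237	SYNT0238	SYNT0239	SYNT0240	SYNT0241
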