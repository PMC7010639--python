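# synthetic 102-sensor ring layout for topography plotting (not a vendor layout)
id	x2d	y2d
MAG000	0.1667	0.0000
MAG001	0.0833	0.1443
MAG002	-0.0833	0.1443
MAG003	-0.1667	0.0000
MAG004	-0.0833	-0.1443
MAG005	0.0833	-0.1443
MAG006	0.3333	0.0000
MAG007	0.2887	0.1667
MAG008	0.1667	0.2887
MAG009	0.0000	0.3333
MAG010	-0.1667	0.2887
MAG011	-0.2887	0.1667
MAG012	-0.3333	0.0000
MAG013	-0.2887	-0.1667
MAG014	-0.1667	-0.2887
MAG015	-0.0000	-0.3333
MAG016	0.1667	-0.2887
MAG017	0.2887	-0.1667
MAG018	0.5000	0.0000
MAG019	0.4698	0.1710
MAG020	0.3830	0.3214
MAG021	0.2500	0.4330
MAG022	0.0868	0.4924
MAG023	-0.0868	0.4924
MAG024	-0.2500	0.4330
MAG025	-0.3830	0.3214
MAG026	-0.4698	0.1710
MAG027	-0.5000	0.0000
MAG028	-0.4698	-0.1710
MAG029	-0.3830	-0.3214
MAG030	-0.2500	-0.4330
MAG031	-0.0868	-0.4924
MAG032	0.0868	-0.4924
MAG033	0.2500	-0.4330
MAG034	0.3830	-0.3214
MAG035	0.4698	-0.1710
MAG036	0.6667	0.0000
MAG037	0.6440	0.1725
MAG038	0.5774	0.3333
MAG039	0.4714	0.4714
MAG040	0.3333	0.5774
MAG041	0.1725	0.6440
MAG042	0.0000	0.6667
MAG043	-0.1725	0.6440
MAG044	-0.3333	0.5774
MAG045	-0.4714	0.4714
MAG046	-0.5774	0.3333
MAG047	-0.6440	0.1725
MAG048	-0.6667	0.0000
MAG049	-0.6440	-0.1725
MAG050	-0.5774	-0.3333
MAG051	-0.4714	-0.4714
MAG052	-0.3333	-0.5774
MAG053	-0.1725	-0.6440
MAG054	-0.0000	-0.6667
MAG055	0.1725	-0.6440
MAG056	0.3333	-0.5774
MAG057	0.4714	-0.4714
MAG058	0.5774	-0.3333
MAG059	0.6440	-0.1725
MAG060	0.8333	0.0000
MAG061	0.8151	0.1733
MAG062	0.7613	0.3389
MAG063	0.6742	0.4898
MAG064	0.5576	0.6193
MAG065	0.4167	0.7217
MAG066	0.2575	0.7925
MAG067	0.0871	0.8288
MAG068	-0.0871	0.8288
MAG069	-0.2575	0.7925
MAG070	-0.4167	0.7217
MAG071	-0.5576	0.6193
MAG072	-0.6742	0.4898
MAG073	-0.7613	0.3389
MAG074	-0.8151	0.1733
MAG075	-0.8333	0.0000
MAG076	-0.8151	-0.1733
MAG077	-0.7613	-0.3389
MAG078	-0.6742	-0.4898
MAG079	-0.5576	-0.6193
MAG080	-0.4167	-0.7217
MAG081	-0.2575	-0.7925
MAG082	-0.0871	-0.8288
MAG083	0.0871	-0.8288
MAG084	0.2575	-0.7925
MAG085	0.4167	-0.7217
MAG086	0.5576	-0.6193
MAG087	0.6742	-0.4898
MAG088	0.7613	-0.3389
MAG089	0.8151	-0.1733
MAG090	1.0000	0.0000
MAG091	0.8660	0.5000
MAG092	0.5000	0.8660
MAG093	0.0000	1.0000
MAG094	-0.5000	0.8660
MAG095	-0.8660	0.5000
MAG096	-1.0000	0.0000
MAG097	-0.8660	-0.5000
MAG098	-0.5000	-0.8660
MAG099	-0.0000	-1.0000
MAG100	0.5000	-0.8660
MAG101	0.8660	-0.5000
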