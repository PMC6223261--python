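name	encoded_seq	mass_mono	gene	species
PLP-1	AIIPGLID	792.475	PawL1b	Zinnia haageana
PLP-2	DLFVPPID	896.464	PawL1c	Senecio pinnatifolius var maritimus
PLP-2	DLFVPPID	896.464	PawL1c	Senecio pinnatifolius ssp latilobus
PLP-3	GSLVYQID	875.439	PawL1a	Senecio pinnatifolius var maritimus
PLP-3	GSLVYQID	875.439	PawL1d	Senecio pinnatifolius var maritimus
PLP-3	GSLVYQID	875.439	PawL1a	Senecio pinnatifolius ssp latilobus
PLP-4	GLLGITD	669.370	PawL1d	Senecio pinnatifolius var maritimus
PLP-4	GLLGITD	669.370	PawL1a	Senecio pinnatifolius ssp latilobus
PLP-5	GLFVD	531.269	PawL1e	Senecio pinnatifolius var maritimus
PLP-6	FFDAAKID	907.444	PawL1b	Senecio pinnatifolius var maritimus
PLP-6	FFDAAKID	907.444	PawL1b	Senecio pinnatifolius ssp latilobus
PLP-7	GLLDVVD	711.380	PawL1a	Senecio pinnatifolius var maritimus
PLP-8	GYPPYYQD	983.402	PawL1a	Zinnia haageana
PLP-9	GLLPPIID	818.490	PawL1a	Zinnia elegans
PLP-10	GSPLFD	616.286	PawL1b	Zinnia elegans
PLP-11	GVYPLGD	701.338	PawL1b	Zinnia elegans
PLP-12	FVGGTSFD	810.355	PawL1b	Senecio vulgaris
PLP-13	TFGVVIAD	802.422	PawL1c	Senecio vulgaris
PLP-14	FVDTTGYD	898.371	PawL1c	Senecio vulgaris
PLP-15	ALVVGLD	667.390	PawL1d	Senecio vulgaris
PLP-16	GLFPYGPD	846.391	PawL1b	Dahlia variabilis
PLP-17	GFPPYVD	775.354	PawL1a	Buphthalum salicifolium
PLP-18	GAIPFPD	697.344	PawL1b	Buphthalum salicifolium
PLP-19	GVLFFPD	775.390	PawL1b	Buphthalum salicifolium
PLP-20	GYLFPD	692.317	PawL1a	Inula racemosa
PLP-20	GYLFPD	692.317	PawL1a	Inula helenium
PLP-21	GYVFPD	678.301	PawL1b	Inula racemosa
PLP-22	GLPPYVD	741.370	PawL1c	Inula racemosa
PLP-22	GLPPYVD	741.370	PawL1b	Inula helenium
PLP-23	YFEEYIHD	1096.450	PawL1a	Othonna arborescens
PLP-24	KYGPPVDFD	1018.476	PawL1b	Othonna arborescens
PLP-25	YYEEYIHD	1112.445	PawL1c	Othonna arborescens
PLP-26	GFPWAPWD	956.418	PawL1c	Melampodium paludosum
PLP-27	AVEPWIPFD	1054.512	PawL1b	Melampodium paludosum
PLP-28	FVETTAGLLD	1046.528	PawL1e	Steirodiscus tagetes
PLP-29	GYFPVGVD	834.391	PawL1g	Steirodiscus tagetes
PLP-30	YIDPAIGKRFGD	1332.683	PawL1b	Cosmos bipinnatus
PLP-31	GVPFPLITHD	1076.565	PawL1b	Engelmannia peristenia
PLP-32	GVLPPMLD	822.431	PawL1a	Arnica chamissonis
PLP-33	GIIVPIVD	806.490	PawL1b	Rudbeckia hirta
PLP-34	GIIIPIVD	820.506	PawL1d	Rudbeckia hirta
PLP-35	GLKFPVVD	855.485	PawL1e	Rudbeckia hirta
PLP-36	AILIPIVD	834.521	PawL1e	Rudbeckia hirta
PLP-37	GFFPADGD	806.323	PawL1g	Rudbeckia hirta
PLP-38	GLYPYPD	805.365	PawL1g	Rudbeckia hirta
PLP-39	IIHLSTPFD	1023.539	PawL1j	Rudbeckia hirta
PLP-40	GILFPIAD	826.459	PawL1m	Rudbeckia hirta
PLP-41	GDVTSPFD	818.345	PawL1a	Sanvitalia procumbens
PLP-42	TFFNPVID	933.460	PawL1c	Sanvitalia procumbens
PLP-43	TLVIPIID	864.532	PawL1d	Sanvitalia procumbens
PLP-44	GWGTPID	726.334	PawL1d	Sanvitalia procumbens
PLP-45	GWITGPWD	912.413	PawL1e	Sanvitalia procumbens
PLP-46	GYITPLD	759.380	PawL1c	Parthenium argentatum
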