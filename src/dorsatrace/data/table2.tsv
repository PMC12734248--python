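specimen	pca_origin	snp_origin	snp_prob	coi_cluster	coi_posterior	coi_origin	consensus
Bd_2023_1	Asia	NA	NA	7	1.0000	Asia	yes
Bd_2023_2	Africa	NA	NA	1	1.0000	Africa	yes
Bd_2023_3	Asia	NA	NA	5	1.0000	Asia	yes
Bd_2023_4	Asia	Asia	1.0000	7	1.0000	Asia	yes
Bd_2023_5	Asia	NA	NA	7	1.0000	Asia	yes
Bd_2023_6	Asia	Asia	1.0000	7	1.0000	Asia	yes
Bd_2023_7	Africa	Africa	1.0000	1	1.0000	Africa	yes
Bd_2024_1	Asia	Asia	1.0000	5	1.0000	Asia	yes
Bd_2024_2	Africa	Africa	1.0000	1	1.0000	Africa	yes
Bd_2024_3	Asia	NA	NA	7	1.0000	Asia	yes
Bd_2024_4	Asia	Asia	1.0000	1	0.9954	Africa	no
FAVV_1	Africa	Africa	1.0000	1	1.0000	Africa	yes
FAVV_2	Africa	NA	NA	1	1.0000	Africa	yes
FAVV_3	Africa	Africa	1.0000	2	1.0000	Africa or South Asia	no
FAVV_4	Africa	Africa	0.9357	1	1.0000	Africa	yes
FAVV_5	Africa	NA	NA	1	1.0000	Africa	yes
FAVV_6	Africa	Africa	1.0000	10	1.0000	Africa	yes
FAVV_7	Africa	Africa	1.0000	10	1.0000	Africa	yes
FAVV_11	Africa	Africa	1.0000	10	1.0000	Africa	yes
FAVV_12	Africa	Africa	1.0000	1	1.0000	Africa	yes
FAVV_13	Africa	Africa	1.0000	10	1.0000	Africa	yes
FAVV_14	Asia	Asia	1.0000	7	1.0000	Asia	yes
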