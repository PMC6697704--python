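name	value	free	lower	upper
kon_HGF_Met	1	0	.	.
koff_HGF_Met	1	0	.	.
kon_Met_Itg	1e-05	1	1e-07	0.001
koff_Met_Itg	0.5	1	0.005	50
kact_Met	0.08	1	0.0008	8
kbasal_act_Met	2e-06	1	2e-08	0.0002
kdephos_pMet_surf	0.02	1	0.0002	2
kdephos_pMet_i	0.008	1	8e-05	0.8
kint_Met	0.01	1	0.0001	1
kint_pMet	0.32	1	0.0032	32
kint_pMetItg	0.085	1	0.00085	8.5
krec_Met	0.04	1	0.0004	4
krec_pMet	0.002	1	2e-05	0.2
krec_pMetItg	0.016	1	0.00016	1.6
kdeg_Met_i	0.005	1	5e-05	0.5
kdeg_pMet_i	0.13	1	0.0013	13
kdeg_pMetItg_i	0.008	1	8e-05	0.8
ksyn_Met	300	1	3	30000
kdeg_Met	0.001	1	1e-05	0.1
ksyn_Itg	500	1	5	50000
kdeg_Itg	0.002	1	2e-05	0.2
kint_Itg	0.02	1	0.0002	2
krec_Itg	0.05	1	0.0005	5
kdeg_Itg_i	0.005	1	5e-05	0.5
kact_Gab1	2.2e-06	1	2.2e-08	0.00022
kdeact_Gab1	0.25	1	0.0025	25
kfb_ERK_Gab1	1	1	0.01	100
kact_Grb2	2.2e-06	1	2.2e-08	0.00022
kdeact_Grb2	0.25	1	0.0025	25
kact_PI3K	2.3e-05	1	2.3e-07	0.0023
kact_PI3K_pERK	1e-08	1	1e-10	1e-06
kdeact_PI3K	0.3	1	0.003	30
kcat_PIP3	5.7e-06	1	5.7e-08	0.00057
kdeg_PIP3	0.3	1	0.003	30
kact_Akt	3.3	1	0.033	330
kdeact_Akt	0.3	1	0.003	30
kact_PDK1	0.5	1	0.005	50
kdeact_PDK1	0.3	1	0.003	30
kact_SOS	4.8e-06	1	4.8e-08	0.00048
kdeact_SOS	0.3	1	0.003	30
kfb_RSK_SOS	2.5	1	0.025	250
kact_Ras	1.85e-05	1	1.85e-07	0.00185
kdeact_Ras	0.5	1	0.005	50
kact_Raf	4.2e-06	1	4.2e-08	0.00042
kdeact_Raf	0.4	1	0.004	40
kfb_ERK_Raf	0.5	1	0.005	50
kfb_Akt_Raf	2	1	0.02	200
kact_MEK	1.3e-05	1	1.3e-07	0.0013
kact_MEK_PDK1	0.02	1	0.0002	2
kdeact_MEK	0.3	1	0.003	30
kact_ERK	1.6e-06	1	1.6e-08	0.00016
kdeact_ERK	0.5	1	0.005	50
kact_RSK	8e-07	1	8e-09	8e-05
kact_RSK_PDK1	0.5	1	0.005	50
kdeact_RSK	0.3	1	0.003	30
kdeact_ppRSK	0.3	1	0.003	30
kon_AXT	0.0001	0	.	.
koff_AXT	1	0	.	.
kstrip_AXT	0.0001	0	.	.
kon_Cabo	0.1	0	.	.
koff_Cabo	0.13	0	.	.
Kd_Rilo	0.5	0	.	.
K_sor	92	1	1	10000
s_sor	1	1	0	1
s_Met	0.9	0	.	.
s_PDK1	0.9	0	.	.
s_MEK	0.9	0	.	.
s_PI3K	0.9	0	.	.
s_ERK	0.9	0	.	.
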