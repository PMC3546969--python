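# Per-residue side-chain properties used as feature channels for substitution mapping.
# volume: mean residue volume in protein interiors (A^3), Zamyatnin (1972).
# charge: formal side-chain charge at neutral pH; histidine defaults to +0.5 (configurable).
# hbond_acceptor / hbond_donor: side-chain hydrogen-bonding capability indicators.
# hydrophobicity: Kyte-Doolittle hydropathy index (larger = more hydrophobic).
# alpha/beta/turn_propensity: Chou-Fasman secondary-structure propensities.
# aromatic: his, phe, trp, tyr. branched: aliphatic beta-branched ile, leu, val.
# crosslink: polar cross-link capable asn, gln, ser, thr.
# ionic: 1 for asp, glu, arg, lys; 0.1 for his; 0 otherwise.
aa	volume	charge	hbond_acceptor	hbond_donor	hydrophobicity	alpha_propensity	beta_propensity	turn_propensity	aromatic	branched	crosslink	ionic
A	88.6	0	0	0	1.8	1.42	0.83	0.66	0	0	0	0
R	173.4	1	0	1	-4.5	0.98	0.93	0.95	0	0	0	1
N	114.1	0	1	1	-3.5	0.67	0.89	1.56	0	0	1	0
D	111.1	-1	1	0	-3.5	1.01	0.54	1.46	0	0	0	1
C	108.5	0	0	0	2.5	0.70	1.19	1.19	0	0	0	0
Q	143.8	0	1	1	-3.5	1.11	1.10	0.98	0	0	1	0
E	138.4	-1	1	0	-3.5	1.51	0.37	0.74	0	0	0	1
G	60.1	0	0	0	-0.4	0.57	0.75	1.56	0	0	0	0
H	153.2	0.5	1	1	-3.2	1.00	0.87	0.95	1	0	0	0.1
I	166.7	0	0	0	4.5	1.08	1.60	0.47	0	1	0	0
L	166.7	0	0	0	3.8	1.21	1.30	0.59	0	1	0	0
K	168.6	1	0	1	-3.9	1.16	0.74	1.01	0	0	0	1
M	162.9	0	0	0	1.9	1.45	1.05	0.60	0	0	0	0
F	189.9	0	0	0	2.8	1.13	1.38	0.60	1	0	0	0
P	112.7	0	0	0	-1.6	0.57	0.55	1.52	0	0	0	0
S	89.0	0	1	1	-0.8	0.77	0.75	1.43	0	0	1	0
T	116.1	0	1	1	-0.7	0.83	1.19	0.96	0	0	1	0
W	227.8	0	0	1	-0.9	1.08	1.37	0.96	1	0	0	0
Y	193.6	0	1	1	-1.3	0.69	1.47	1.14	1	0	0	0
V	140.0	0	0	0	4.2	1.06	1.70	0.50	0	1	0	0
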