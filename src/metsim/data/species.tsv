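# Thermodynamic and transport properties of the chemical species used by the
# two shipped case studies.  One row per species.
# Columns:
#   name      identifier used in stoichiometries and state maps
#   charge    elementary charges
#   dGf0      standard Gibbs energy of formation, kJ/mol, 298.15 K, aqueous
#             standard state (1 mol/L) unless the species is the solvent
#   dHf0      standard enthalpy of formation, kJ/mol (used only for T != 298.15 K)
#   elements  element:count pairs, comma separated (counts may be rational for
#             the lumped biomass composition CH1.8O0.5N0.2)
#   role      solvent | aqueous | biomass | electron
#   lambda0   limiting molar conductivity, S*cm2/mol (0 for neutral species)
#   perm      relative membrane permeability (dimensionless, before the
#             membrane-type rules zero out the excluded charge sign)
#   source    literature source of dGf0/dHf0
name	charge	dGf0	dHf0	elements	role	lambda0	perm	source
h2o	0	-237.18	-285.83	H:2,O:1	solvent	0	0	Thauer1977
h+	1	0.0	0.0	H:1	aqueous	349.8	1	convention
oh-	-1	-157.30	-230.00	H:1,O:1	aqueous	198.0	1	Thauer1977
acetate	-1	-369.41	-486.0	C:2,H:3,O:2	aqueous	40.9	1	Thauer1977
acetic_acid	0	-396.60	-485.8	C:2,H:4,O:2	aqueous	0	0	Thauer1977
butyrate	-1	-352.63	-535.6	C:4,H:7,O:2	aqueous	32.6	1	Thauer1977
butyric_acid	0	-380.13	-533.9	C:4,H:8,O:2	aqueous	0	0	Thauer1977+pKa4.82
co2_aq	0	-386.00	-413.8	C:1,O:2	aqueous	0	0	Thauer1977
hco3-	-1	-586.85	-692.0	C:1,H:1,O:3	aqueous	44.5	1	Thauer1977
co3--	-2	-527.90	-677.1	C:1,O:3	aqueous	138.6	0.5	Thauer1977
nh4+	1	-79.37	-132.5	N:1,H:4	aqueous	73.5	1	Thauer1977
nh3_aq	0	-26.57	-80.3	N:1,H:3	aqueous	0	0	Thauer1977
h2_aq	0	17.57	-4.2	H:2	aqueous	0	0	Thauer1977(aq basis)
ch4_aq	0	-34.39	-89.0	C:1,H:4	aqueous	0	0	Thauer1977(aq basis)
ethanol	0	-181.75	-288.3	C:2,H:6,O:1	aqueous	0	0	Thauer1977
butanol	0	-162.50	-327.3	C:4,H:10,O:1	aqueous	0	0	CRC(l),transfer~0 at ~1M solubility
clo4-	-1	-8.52	-129.3	Cl:1,O:4	aqueous	67.3	0.7	CRC
clo3-	-1	-7.95	-104.0	Cl:1,O:3	aqueous	64.6	0.8	CRC
clo2-	-1	17.20	-66.5	Cl:1,O:2	aqueous	52.0	0.9	CRC
clo-	-1	-36.80	-107.1	Cl:1,O:1	aqueous	47.0	0.9	CRC
hclo	0	-79.90	-120.9	Cl:1,H:1,O:1	aqueous	0	0	CRC
cl-	-1	-131.26	-167.2	Cl:1	aqueous	76.3	1	CRC
na+	1	-261.90	-240.1	Na:1	aqueous	50.1	1	CRC
k+	1	-283.30	-252.4	K:1	aqueous	73.5	1	CRC
biomass	0	-67.0	-91.0	C:1,H:9/5,O:1/2,N:1/5	biomass	0	0	Heijnen1994(per mol C)
inert	0	-67.0	-91.0	C:1,H:9/5,O:1/2,N:1/5	biomass	0	0	decay product, biomass composition
e-	-1	0.0	0.0		electron	0	0	convention
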