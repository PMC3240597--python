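name	value	unit	description
V1max	0.09874985976	a.u./h	Per basal transcription rate
V2max	0.1244637182	a.u./h	Cry basal transcription rate
V3max	3.625580346	a.u./h	Rev-Erb basal transcription rate
V4max	0.1454479172	a.u./h	Ror basal transcription rate
V5max	3.003006562	a.u./h	Bmal basal transcription rate
ka1	1.7	a.u.	CLOCK/BMAL activation constant, Per promoter
ka2	1.7	a.u.	CLOCK/BMAL activation constant, Cry promoter
ka3	2.55	a.u.	CLOCK/BMAL activation constant, Rev-Erb promoter
ka4	0.9	a.u.	CLOCK/BMAL activation constant, Ror promoter
ka5	3.100756534	a.u.	ROR_N activation constant, Bmal RORE
b1	3	1	activation Hill coefficient, Per
b2	3	1	activation Hill coefficient, Cry
b3	4	1	activation Hill coefficient, Rev-Erb
b4	2	1	activation Hill coefficient, Ror
b5	2	1	activation Hill coefficient, Bmal
f1	10	1	fold activation, Per
f2	8	1	fold activation, Cry
f3	7.5	1	fold activation, Rev-Erb
f4	6	1	fold activation, Ror
f5	5	1	fold activation, Bmal
ki1	1.537034158	a.u.	PER/CRY pool inhibition constant, Per
ki2	1.570176043	a.u.	PER/CRY pool inhibition constant, Cry
ki3	3.608227753	a.u.	PER/CRY pool inhibition constant, Rev-Erb
ki4	2.589274065	a.u.	PER/CRY pool inhibition constant, Ror
ki5	0.5149390395	a.u.	REV-ERB_N inhibition constant, Bmal RORE
ki6	441.869353	a.u.	REV-ERB_N inhibition constant, Cry
c1	4	1	inhibition Hill coefficient, Per
c2	4	1	inhibition Hill coefficient, Cry
c3	2	1	inhibition Hill coefficient, Rev-Erb
c4	2	1	inhibition Hill coefficient, Ror
c5	4	1	inhibition Hill coefficient, Bmal RORE
c6	3	1	inhibition Hill coefficient, Cry by REV-ERB_N
kp1	1.0863707	1/h	Per translation rate
kp2	1.236593608	1/h	Cry translation rate
kp3	1.60476444	1/h	Rev-Erb translation rate
kp4	0.1344673546	1/h	Ror translation rate
kp5	1.090976941	1/h	Bmal translation rate
kphos	0.06076155113	1/h	PER_C phosphorylation
kdphos	0.1936850485	1/h	PERp_C dephosphorylation
kfz4	0.4800496641	1/(a.u. h)	PERp_C + CRY_C association
kdz4	0.1189027956	1/h	PERp/CRY_C dissociation
kfz5	0.3651571341	1/(a.u. h)	PER_C + CRY_C association
kdz5	0.0545951336	1/h	PER/CRY_C dissociation
kfx1	0.3085105978	1/h	CLOCK/BMAL formation from BMAL_N (CLOCK absorbed)
kdx1	0.0128416639	1/h	CLOCK/BMAL dissociation
kiz4	0.02139603909	1/h	PERp/CRY_C nuclear import
kiz5	0.1682811093	1/h	PER/CRY_C nuclear import
kiz6	0.4045317871	1/h	REV-ERB_C nuclear import
kiz7	0.01514655371	1/h	ROR_C nuclear import
kiz8	0.2335465522	1/h	BMAL_C nuclear import
kex1	0.01104174677	1/h	PER/CRY_N nuclear export
kex2	0.02	1/h	PERp/CRY_N nuclear export
dy1	0.3	1/h	Per mRNA degradation
dy2	0.1702375427	1/h	Cry mRNA degradation
dy3	6.55161242	1/h	Rev-Erb mRNA degradation
dy4	0.4622693127	1/h	Ror mRNA degradation
dy5	1.190030405	1/h	Bmal mRNA degradation
dz1	0.15	1/h	PER_C degradation
dz2	0.15	1/h	PERp_C degradation
dz3	0.8	1/h	CRY_C degradation
dz4	0.15	1/h	PERp/CRY_C degradation
dz5	0.15	1/h	PER/CRY_C degradation
dz6	0.1579715619	1/h	REV-ERB_C degradation
dz7	0.007627813513	1/h	ROR_C degradation
dz8	0.1099508536	1/h	BMAL_C degradation
dx1	0.2884908203	1/h	CLOCK/BMAL degradation
dx2	0.08103195856	1/h	PERp/CRY_N degradation
dx3	0.2109664296	1/h	PER/CRY_N degradation
dx4	0.05087290817	1/h	BMAL_N degradation
dx5	0.5712941526	1/h	REV-ERB_N degradation
dx6	0.01531073761	1/h	ROR_N degradation
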