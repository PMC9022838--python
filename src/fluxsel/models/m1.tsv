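#substrate PYR.ext GLN.ext CO2.in AC.unl
#sink CO2
#measured PYR CIT ACON AKG GLU GLN FUM MAL ASP
reaction_id	equation	reversible	notes
PYRT	PYR.ext(abc) -> PYR(abc)	0	pyruvate uptake (normalized to 1)
GLNT	GLN.ext(abcde) -> GLN(abcde)	0	glutamine uptake
PDH	PYR(abc) -> ACCOA(bc) + CO2(a)	0	pyruvate dehydrogenase
CS	ACCOA(ab) + OAA(cdef) -> CIT(fedcba)	0	citrate synthase
ACONT1m	CIT(abcdef) -> ACON(abcdef)	0	aconitase, citrate -> cis-aconitate
ACONT2m_IDH	ACON(abcdef) -> AKG(abcde) + CO2(f)	0	cis-aconitate -> isocitrate -> AKG (lumped)
GLS	GLN(abcde) -> GLU(abcde)	0	glutaminase
GDH	GLU(abcde) -> AKG(abcde)	0	glutamate dehydrogenase
OGDH	AKG(abcde) -> 0.5 FUM(bcde) + 0.5 FUM(edcb) + CO2(a)	0	AKG -> succinate -> fumarate (lumped, symmetric scrambling)
FUMm	FUM(abcd) -> 0.5 MAL(abcd) + 0.5 MAL(dcba)	0	fumarase (symmetric substrate)
MDH	MAL(abcd) -> OAA(abcd)	0	malate dehydrogenase
GOT	OAA(abcd) -> ASP(abcd)	0	aspartate transaminase
ASCm	ACCOA(ab) -> AC(ab)	0	acetyl-CoA hydrolysis / acetate release
PYR_ef	PYR ->	0	efflux
CIT_ef	CIT ->	0	efflux
ACON_ef	ACON ->	0	efflux
AKG_ef	AKG ->	0	efflux
GLU_ef	GLU ->	0	efflux
GLN_ef	GLN ->	0	efflux
FUM_ef	FUM ->	0	efflux
MAL_ef	MAL ->	0	efflux
ASP_ef	ASP ->	0	efflux
AC_ef	AC ->	0	efflux
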