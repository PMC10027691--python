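name	area	hemisphere	n_subrois	role	inferred
Lbankssts	bankssts	left	16	activation	1
Lcaudalanteriorcingulate	caudalanteriorcingulate	left	16	activation	1
Lcaudalmiddlefrontal	caudalmiddlefrontal	left	16	activation	1
Lcuneus	cuneus	left	16	activation	1
Lentorhinal	entorhinal	left	16	activation	1
Lfusiform	fusiform	left	16	activation	1
Linferiorparietal	inferiorparietal	left	16	activation	1
Linferiortemporal	inferiortemporal	left	16	activation	1
Listhmuscingulate	isthmuscingulate	left	16	activation	1
Llateraloccipital	lateraloccipital	left	16	activation	1
Llateralorbitofrontal	lateralorbitofrontal	left	16	activation	1
Llingual	lingual	left	16	activation	1
Lmedialorbitofrontal	medialorbitofrontal	left	16	activation	1
Lmiddletemporal	middletemporal	left	16	activation	1
Lparahippocampal	parahippocampal	left	16	activation	1
Lparacentral	paracentral	left	16	activation	1
Lparsopercularis	parsopercularis	left	16	activation	1
Lparsorbitalis	parsorbitalis	left	16	activation	1
Lparstriangularis	parstriangularis	left	16	activation	1
Lpericalcarine	pericalcarine	left	16	activation	1
Lposteriorcingulate	posteriorcingulate	left	16	activation	1
Lprecuneus	precuneus	left	16	activation	1
Lrostralanteriorcingulate	rostralanteriorcingulate	left	16	activation	1
Lrostralmiddlefrontal	rostralmiddlefrontal	left	16	activation	1
Lsuperiorfrontal	superiorfrontal	left	16	activation	1
Lsuperiorparietal	superiorparietal	left	16	activation	1
Lsupramarginal	supramarginal	left	16	activation	1
Lfrontalpole	frontalpole	left	16	activation	1
Ltemporalpole	temporalpole	left	16	activation	1
Linsula	insula	left	16	activation	1
LHG	HG	left	16	activation	1
LHS	HS	left	16	activation	1
LPT	PT	left	16	activation	1
LpSTG	pSTG	left	16	activation	1
LaSTG	aSTG	left	16	activation	1
LLF	LF	left	16	activation	1
LiCS	iCS	left	16	activation	1
LSTS	STS	left	16	activation	1
LPP	PP	left	16	activation	1
LvPreC	vPreC	left	16	activation	1
LdPreC	dPreC	left	16	activation	1
LvPostC	vPostC	left	16	activation	1
LdPostC	dPostC	left	16	activation	1
Rbankssts	bankssts	right	16	activation	1
Rcaudalanteriorcingulate	caudalanteriorcingulate	right	16	activation	1
Rcaudalmiddlefrontal	caudalmiddlefrontal	right	16	activation	1
Rcuneus	cuneus	right	16	activation	1
Rentorhinal	entorhinal	right	16	activation	1
Rfusiform	fusiform	right	16	activation	1
Rinferiorparietal	inferiorparietal	right	16	activation	1
Rinferiortemporal	inferiortemporal	right	16	activation	1
Risthmuscingulate	isthmuscingulate	right	16	activation	1
Rlateraloccipital	lateraloccipital	right	16	activation	1
Rlateralorbitofrontal	lateralorbitofrontal	right	16	activation	1
Rlingual	lingual	right	16	activation	1
Rmedialorbitofrontal	medialorbitofrontal	right	16	activation	1
Rmiddletemporal	middletemporal	right	16	activation	1
Rparahippocampal	parahippocampal	right	16	activation	1
Rparacentral	paracentral	right	16	activation	1
Rparsopercularis	parsopercularis	right	16	activation	1
Rparsorbitalis	parsorbitalis	right	16	activation	1
Rparstriangularis	parstriangularis	right	16	activation	1
Rpericalcarine	pericalcarine	right	16	activation	1
Rposteriorcingulate	posteriorcingulate	right	16	activation	1
Rprecuneus	precuneus	right	16	activation	1
Rrostralanteriorcingulate	rostralanteriorcingulate	right	16	activation	1
Rrostralmiddlefrontal	rostralmiddlefrontal	right	16	activation	1
Rsuperiorfrontal	superiorfrontal	right	16	activation	1
Rsuperiorparietal	superiorparietal	right	16	activation	1
Rsupramarginal	supramarginal	right	16	activation	1
Rfrontalpole	frontalpole	right	16	activation	1
Rtemporalpole	temporalpole	right	16	activation	1
Rinsula	insula	right	16	activation	1
RHG	HG	right	16	activation	1
RHS	HS	right	16	activation	1
RPT	PT	right	16	activation	1
RpSTG	pSTG	right	16	activation	1
RaSTG	aSTG	right	16	activation	1
RLF	LF	right	16	activation	1
RiCS	iCS	right	16	activation	1
RSTS	STS	right	16	activation	1
RPP	PP	right	16	activation	1
RvPreC	vPreC	right	16	activation	1
RdPreC	dPreC	right	16	activation	1
RvPostC	vPostC	right	16	activation	1
RdPostC	dPostC	right	16	activation	1
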