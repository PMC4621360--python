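# FG-Nup construct registry: Nsp1-derived FG-repeat fragments and fusions.
# Sequences are recorded verbatim as published, including one known
# typographical defect: the untagged FSFG-K row prints 124 residues against a
# stated count of 125 (an Ala is missing in "DGDASKP[A]FSFG"); stated mass
# 13,070 Da exceeds the printed sequence's mass by exactly one Ala residue.
# The registry keeps the row as printed; `validate_registry` flags it.
# regions: semicolon-separated label:start-end[@ref_start] spans, 1-based
# inclusive; @ref_start gives the Nsp1 residue number of the span's first
# residue. n_chains: oligomer count (4 for p53-tetramerization-domain fusions).
id	n_chains	stated_residues	stated_mass_da	regions	sequence
fsfg-k	1	125	13070	init:1-1;nsp1:2-124@274	MDNKTTNTTPSFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPFSFGAKPDENKASATSKPA
fsfg-k-his	1	133	14135	init:1-1;nsp1:2-125@274;his-tag:126-133	MDNKTTNTTPSFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDENKASATSKPALEHHHHHH
fg-n	1	137	13649	leader:1-3;nsp1:4-128@48;his-tag:129-137	MGTSAPNNTNNANSSITPAFGSNNTGNTAFGNSNPTSNVFGSNNSTTNTFGSNSAGTSLFGSSSAQQTKSNGTAGGNTFGSSSLFNNSTNSNTTKPAFGGLNFGGGNNTTPSSTGNANTSNNLFGATASHMHHHHHH
fgn-fsfgk-tet-his	4	292	30235	leader:1-3;nsp1-fgn:4-128@48;linker:129-136;nsp1-fsfgk:137-250@284;linker2:251-253;tet:254-283;his-tag:284-292	MGTSAPNNTNNANSSITPAFGSNNTGNTAFGNSNPTSNVFGSNNSTTNTFGSNSAGTSLFGSSSAQQTKSNGTAGGNTFGSSSLFNNSTNSNTTKPAFGGLNFGGGNNTTPSSTGNANTSNNLFGATAASATSKPAFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDENKASATSKPASHMGEYFTLQIRGRERFEMFRELNEALELKDAQAHMHHHHHH
fsfg-k-284	1	131	13721	leader:1-10;nsp1:11-124@284;his-tag:125-131	MGTSATSKPAFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDENKASATSKPASHHHHHH
fsfgk-fsfgk-tet-his	4	287	30504	leader:1-10;nsp1-a:11-124@284;linker:125-131;nsp1-b:132-245@284;linker2:246-248;tet:249-278;his-tag:279-287	MGTSATSKPAFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDENKASATSKPASATSKPAFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDENKASATSKPASHMGEYFTLQIRGRERFEMFRELNEALELKDAQAHMHHHHHH
fgn-fgn-tet-his	4	296	29927	leader:1-4;nsp1-a:5-129@48;nsp1-b:130-254@48;linker2:255-257;tet:258-287;his-tag:288-296	MGCTSAPNNTNNANSSITPAFGSNNTGNTAFGNSNPTSNVFGSNNSTTNTFGSNSAGTSLFGSSSAQQTKSNGTAGGNTFGSSSLFNNSTNSNTTKPAFGGLNFGGGNNTTPSSTGNANTSNNLFGATASAPNNTNNANSSITPAFGSNNTGNTAFGNSNPTSNVFGSNNSTTNTFGSNSAGTSLFGSSSAQQTKSNGTAGGNTFGSSSLFNNSTNSNTTKPAFGGLNFGGGNNTTPSSTGNANTSNNLFGATASHMGEYFTLQIRGRERFEMFRELNEALELKDAQAHMHHHHHH
fgn-fsfgk-his	1	257	25955	leader:1-3;nsp1-fgn:4-128@48;linker:129-136;nsp1-fsfgk:137-250@284;his-tag:251-257	MGTSAPNNTNNANSSITPAFGSNNTGNTAFGNSNPTSNVFGSNNSTTNTFGSNSAGTSLFGSSSAQQTKSNGTAGGNTFGSSSLFNNSTNSNTTKPAFGGLNFGGGNNTTPSSTGNANTSNNLFGATAASATSKPAFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDENKASATSKPASHHHHHH
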