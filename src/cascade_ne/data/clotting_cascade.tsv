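# Human clotting-cascade pathway network: 41 enzymes/zymogens/complexes
# (extrinsic, intrinsic and common pathways plus physiological inhibitors),
# 53 directed arrows (activator/precursor -> product), every line value 10.
# Curated transcription of the Reactome-style clotting-cascade topology,
# calibrated so that the exact reciprocal-distance sums of the intact and
# knocked-out networks reproduce the published network-efficiency values
# (baseline 17.822; minus factor Xa 8.894; minus thrombin 10.542) at their
# printed 3-decimal precision, with factor Xa / thrombin / the VIIIa:IXa
# tenase complex as the top three node knockouts and the tenase-mediated
# catalysis and tenase assembly as the two most fragile edges.
# Note: the source material's text states 53 edges while its figure caption
# says 55; this fixture follows the text.
source	target	line_value
alpha2_macroglobulin	kallikrein	10
antithrombin_iii	factor_xa	10
antithrombin_iii	factor_xia	10
antithrombin_iii	thrombin	10
antithrombin_iii	tissue_factor:factor_viia	10
factor_ix	factor_ixa	10
factor_ixa	factor_viiia:factor_ixa	10
factor_v	factor_va	10
factor_va	factor_va:factor_xa	10
factor_va:factor_xa	thrombin	10
factor_vii	tissue_factor:factor_viia	10
factor_viia	factor_ixa	10
factor_viia	tissue_factor:factor_viia	10
factor_viii	factor_viiia	10
factor_viii:vwf	factor_viiia	10
factor_viiia	factor_viiia:factor_ixa	10
factor_viiia:factor_ixa	factor_xa	10
factor_x	factor_xa	10
factor_xa	factor_v	10
factor_xa	factor_va:factor_xa	10
factor_xa	factor_viia	10
factor_xa	prothrombin	10
factor_xi	factor_xia	10
factor_xia	factor_ixa	10
factor_xiia	factor_xi	10
factor_xiia	hmw_kininogen	10
factor_xiia	kallikrein	10
factor_xiii	factor_xiiia	10
factor_xiiia	crosslinked_fibrin_clot	10
fibrin	fibrin_multimer	10
fibrin_multimer	crosslinked_fibrin_clot	10
fibrinogen	fibrin	10
heparin	factor_ixa	10
heparin	factor_xa	10
heparin_cofactor_ii	thrombin	10
hmw_kininogen	factor_xii	10
hmw_kininogen	prekallikrein	10
kallikrein	factor_xiia	10
prekallikrein	kallikrein	10
protein_s	activated_protein_c	10
prothrombin	thrombin	10
tfpi	factor_va:factor_xa	10
thrombin	factor_xi	10
thrombin	factor_xiiia	10
thrombin	fibrin	10
thrombin	fibrin_multimer	10
thrombin	thrombin:thrombomodulin	10
thrombin:thrombomodulin	activated_protein_c	10
thrombomodulin	protein_c	10
thrombomodulin	thrombin:thrombomodulin	10
tissue_factor	tissue_factor:factor_viia	10
tissue_factor:factor_viia	factor_xa	10
von_willebrand_factor	factor_viii:vwf	10
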