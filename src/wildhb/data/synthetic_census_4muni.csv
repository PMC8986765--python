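municipality_id,pop_2010,pop_2019,rural_fraction,children_6m_5y,households_total,hh_no_income,hh_income_le_eighth_mw,hh_income_eighth_to_quarter_mw,hh_income_quarter_to_half_mw,hh_income_above_half_mw
U01,57232,68749,0.662,5979,11609,1351,5247,2473,1919,619
U02,46122,53427,0.705,3693,10540,956,4491,2897,1533,663
U03,39579,43819,0.64,4184,7817,934,2497,2468,915,1003
U04,27028,31864,0.777,2189,5700,994,2554,1309,358,485
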