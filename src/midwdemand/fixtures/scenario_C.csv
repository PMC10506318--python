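trajectory_id,unit,rule,year,value,source
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2011,1.0,administrative
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2016,1.4,administrative
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2021,1.9,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2026,2.4,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2031,3.4,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2036,4.5,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2041,6.0,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2011,1.0,administrative
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2016,1.4,administrative
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2021,2.0,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2026,2.6,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2031,4.0,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2036,5.7,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2041,8.0,elicitation
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2011,0.8,administrative
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2016,3.4,administrative
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2021,3.0,elicitation
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2026,2.7,elicitation
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2031,2.3,elicitation
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2036,1.9,elicitation
n_prenatal_modhigh,sessions,piecewise_linear_then_constant,2041,1.6,elicitation
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2011,0.3,administrative
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2016,0.6,administrative
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2021,0.7,elicitation
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2026,0.7,elicitation
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2031,0.8,elicitation
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2036,0.9,elicitation
n_birthprep_ind[multiparous],sessions,piecewise_linear_then_constant,2041,1.0,elicitation
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2011,0.3,administrative
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2016,0.6,administrative
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2021,0.8,elicitation
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2026,1.1,elicitation
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2031,1.6,elicitation
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2036,2.2,elicitation
n_birthprep_ind[primiparous],sessions,piecewise_linear_then_constant,2041,3.0,elicitation
n_birthprep_group[multiparous],sessions,piecewise_linear_then_constant,2011,0.3,administrative
n_birthprep_group[multiparous],sessions,piecewise_linear_then_constant,2016,0.4,administrative
n_birthprep_group[multiparous],sessions,piecewise_linear_then_constant,2021,0.2,elicitation
n_birthprep_group[multiparous],sessions,piecewise_linear_then_constant,2041,0.2,elicitation
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2011,0.3,administrative
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2016,0.4,administrative
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2021,0.5,elicitation
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2026,0.6,elicitation
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2031,0.7,elicitation
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2036,0.8,elicitation
n_birthprep_group[primiparous],sessions,piecewise_linear_then_constant,2041,0.9,elicitation
coordination_uplift,percent,piecewise_linear_then_constant,2016,20,elicitation
coordination_uplift,percent,piecewise_linear_then_constant,2021,21,elicitation
coordination_uplift,percent,piecewise_linear_then_constant,2026,22,elicitation
coordination_uplift,percent,piecewise_linear_then_constant,2031,23,elicitation
coordination_uplift,percent,piecewise_linear_then_constant,2036,24,elicitation
coordination_uplift,percent,piecewise_linear_then_constant,2041,25,elicitation
n_postnatal_d6plus[multiparous],services,piecewise_linear_then_constant,2011,0.9,administrative
n_postnatal_d6plus[multiparous],services,piecewise_linear_then_constant,2016,1.7,administrative
n_postnatal_d6plus[multiparous],services,piecewise_linear_then_constant,2021,4.0,elicitation
n_postnatal_d6plus[multiparous],services,piecewise_linear_then_constant,2041,4.0,elicitation
n_postnatal_d6plus[primiparous],services,piecewise_linear_then_constant,2011,0.9,administrative
n_postnatal_d6plus[primiparous],services,piecewise_linear_then_constant,2016,1.7,administrative
n_postnatal_d6plus[primiparous],services,piecewise_linear_then_constant,2021,7.0,elicitation
n_postnatal_d6plus[primiparous],services,piecewise_linear_then_constant,2041,7.0,elicitation
alos[560][1][25_34],days,piecewise_linear_then_constant,2011,4.1,administrative
alos[560][1][25_34],days,piecewise_linear_then_constant,2016,3.7,administrative
alos[560][1][25_34],days,piecewise_linear_then_constant,2021,3.0,elicitation
alos[560][1][25_34],days,piecewise_linear_then_constant,2026,2.0,elicitation
alos[560][1][35_39],days,piecewise_linear_then_constant,2011,4.0,administrative
alos[560][1][35_39],days,piecewise_linear_then_constant,2016,3.6,administrative
alos[560][1][35_39],days,piecewise_linear_then_constant,2021,3.0,elicitation
alos[560][1][35_39],days,piecewise_linear_then_constant,2026,2.0,elicitation
alos[560][2][25_34],days,piecewise_linear_then_constant,2011,5.1,synthetic_default
alos[560][2][25_34],days,piecewise_linear_then_constant,2016,4.6,synthetic_default
alos[560][2][25_34],days,piecewise_linear_then_constant,2021,3.7,elicitation
alos[560][2][25_34],days,piecewise_linear_then_constant,2026,2.5,elicitation
alos[560][2][35_39],days,piecewise_linear_then_constant,2011,5.1,synthetic_default
alos[560][2][35_39],days,piecewise_linear_then_constant,2016,4.6,synthetic_default
alos[560][2][35_39],days,piecewise_linear_then_constant,2021,3.7,elicitation
alos[560][2][35_39],days,piecewise_linear_then_constant,2026,2.5,elicitation
alos[540][1][25_34],days,piecewise_linear_then_constant,2011,5.7,administrative
alos[540][1][25_34],days,piecewise_linear_then_constant,2016,5.0,administrative
alos[540][1][25_34],days,piecewise_linear_then_constant,2021,4.4,elicitation
alos[540][1][25_34],days,piecewise_linear_then_constant,2026,3.0,elicitation
alos[540][1][35_39],days,piecewise_linear_then_constant,2011,5.7,administrative
alos[540][1][35_39],days,piecewise_linear_then_constant,2016,5.1,administrative
alos[540][1][35_39],days,piecewise_linear_then_constant,2021,4.4,elicitation
alos[540][1][35_39],days,piecewise_linear_then_constant,2026,3.0,elicitation
alos[540][2][25_34],days,piecewise_linear_then_constant,2011,7.7,synthetic_default
alos[540][2][25_34],days,piecewise_linear_then_constant,2016,6.8,synthetic_default
alos[540][2][25_34],days,piecewise_linear_then_constant,2021,5.4,elicitation
alos[540][2][25_34],days,piecewise_linear_then_constant,2026,4.0,elicitation
alos[540][2][35_39],days,piecewise_linear_then_constant,2011,7.7,synthetic_default
alos[540][2][35_39],days,piecewise_linear_then_constant,2016,6.8,synthetic_default
alos[540][2][35_39],days,piecewise_linear_then_constant,2021,5.4,elicitation
alos[540][2][35_39],days,piecewise_linear_then_constant,2026,4.0,elicitation
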