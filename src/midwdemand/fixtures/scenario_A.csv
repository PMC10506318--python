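trajectory_id,unit,rule,year,value,source
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2011,1.0,administrative
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2016,1.4,administrative
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2021,1.6,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2026,1.8,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2031,2.2,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2036,2.6,elicitation
n_prenatal_low[multiparous],sessions,piecewise_linear_then_constant,2041,3.0,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2011,1.0,administrative
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2016,1.4,administrative
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2021,1.8,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2026,2.2,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2031,3.0,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2036,3.4,elicitation
n_prenatal_low[primiparous],sessions,piecewise_linear_then_constant,2041,5.0,elicitation
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
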