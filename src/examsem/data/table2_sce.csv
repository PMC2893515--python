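exam,diet,n_scored_items,alpha,sd,sem,n_candidates
Gastroenterology,2008,200,0.84,7.00,2.80,8
Dermatology,2009,200,0.88,7.27,2.52,39
Endocrinology and Diabetes,2009,200,0.89,9.03,2.99,39
Geriatric Medicine,2009,200,0.48,3.97,2.86,15
Infectious Diseases,2009,200,0.94,12.13,2.97,6
Neurology,2009,200,0.89,9.13,3.03,25
Nephrology,2009,200,0.86,7.80,2.92,33
Respiratory Medicine,2009,200,0.85,7.47,2.89,25
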