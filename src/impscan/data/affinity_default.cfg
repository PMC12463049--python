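# Default parameters of the contact-based binding free-energy model.
# dG = sum_k w_ic[k] * IC[k] + w_nis_apolar * %NIS_apolar
#      + w_nis_charged * %NIS_charged + intercept   [kcal/mol]
# Coefficients reproduce the published contact-based consensus model
# (Vangone & Bonvin 2015); contact classes without a term carry weight 0.
w_cc = -0.09459
w_cp = 0.0
w_ca = -0.10007
w_pp = 0.19577
w_pa = -0.22671
w_aa = 0.0
w_nis_apolar = 0.18681
w_nis_charged = 0.13810
intercept = -15.9433
provenance = contact-based consensus model (Vangone & Bonvin 2015)
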