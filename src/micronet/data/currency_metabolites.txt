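# Common currency (cofactor) metabolites, per compartment, for the optional
# exclusion list of `micronet graph --exclude-currency` and
# build_metabolite_graph(exclude=...).  Removing these hub compounds from
# the metabolite graph materially changes SCC structure, which is why the
# exclusion is OFF by default and must be requested explicitly.
h2o_c
h2o_e
h_c
h_e
atp_c
adp_c
amp_c
pi_c
ppi_c
nad_c
nadh_c
nadp_c
nadph_c
co2_c
co2_e
coa_c
nh4_c
o2_c
o2_e
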