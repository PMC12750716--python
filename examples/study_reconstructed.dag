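# Synthetic reconstruction of the a-priori mediation diagram for the
# nurse-helpfulness -> breastfeeding-self-efficacy -> exclusivity analysis.
# The published diagram is not machine-readable, so the confounder edges
# below are a plausible reconstruction, not the authors' exact graph; the
# pipeline accepts any user-supplied DAG in this format.

exposure: x_helpful
mediator: bses_total
outcome: y_exclusive

# causal paths
x_helpful -> bses_total
bses_total -> y_exclusive
x_helpful -> y_exclusive

# confounders of the exposure
hps_high -> x_helpful; hps_high -> bses_total; hps_high -> y_exclusive
educ_grade12 -> x_helpful; educ_grade12 -> bses_total; educ_grade12 -> y_exclusive
assets -> x_helpful; assets -> y_exclusive

# causes of mediator and outcome only
age -> parity; age -> bses_total; age -> y_exclusive
parity -> bses_total
caesarean -> bses_total; caesarean -> y_exclusive
hiv -> y_exclusive
infant_age -> bses_total; infant_age -> y_exclusive
employed -> y_exclusive
hsi_high -> y_exclusive
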