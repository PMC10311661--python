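# Demo discovery run: small planted-truth simulation through all six stages.
seed: 7
out_dir: scratch/demo_run
cohort:
  n_patients: 150
  n_genes: 500
  n_signature_genes: 40
  sl_partner_gene: PLK1
  sl_interaction_beta: 1.2
connect:
  n_decoys: 10
synergy:
  combo_alpha: 0.5
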