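# The "heterogeneous-17" benchmark regime: 17 constituent algorithms whose
# baseline call rates span logistic(a) ~ 0.001-0.05 and whose reliabilities b
# span true-LDO recall ~ 0.3-0.95 (a fixed interleaving decouples the two),
# with a shared pair-level latent (sd 1.0) correlating the calls and a
# conservative reference covering 80% of planted LDOs with 2% contamination.
# Consumed by:  ldometa simulate --config <this file> --out <dir>
n_query_genes: 3000
n_target_genes: 3000
family_size_distribution:
  1: 0.6
  2: 0.25
  3: 0.1
  4: 0.05
frac_families_with_true_ldo: 0.9
K: 17
a:
- -6.906755
- -6.65911
- -6.411465
- -6.163821
- -5.916176
- -5.668531
- -5.420886
- -5.173242
- -4.925597
- -4.677952
- -4.430307
- -4.182663
- -3.935018
- -3.687373
- -3.439728
- -3.192084
- -2.944439
b:
- 6.059457
- 6.99673
- 7.934003
- 8.871276
- 5.779829
- 6.717102
- 7.654375
- 4.562927
- 5.5002
- 6.437473
- 7.374746
- 4.283299
- 5.220572
- 6.157845
- 3.066398
- 4.003671
- 4.940944
paralog_boost: 2.0
latent_sd: 1.0
background_rate: 0.5
reference_recall: 0.8
reference_fpr: 0.02
seed: 0
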