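# Demo scenario for `mitodnv full --config examples/demo.yaml`.
# Every stochastic stage derives its seed from the single top-level seed.

seed: 7
out_dir: demo_out

# synthetic cohort scenario
n_genes: 400        # analyzed gene universe
n_udd: 6000         # probands, first case cohort
n_asd: 2000         # probands, second case cohort
n_control: 1500     # unaffected controls
pi: 0.05            # prior / generating fraction of risk genes
gamma_mean_ptv: 20.0   # mean relative risk of a risk gene, PTV class
gamma_mean_dmis: 8.0   # mean relative risk, deleterious missense
beta: 1.0           # Gamma-prior rate parameter
log_mu_mean: -11.0  # natural-log mean of per-gene missense mutation rates
log_mu_sd: 1.0
risk_boost: 0.4     # extra PPI edge probability among risk-gene pairs
n_pre: 20           # prenatal expression samples
n_post: 20          # postnatal expression samples
expression_effect: 1.0  # prenatal log2-mean shift for risk genes

# analysis thresholds
dmis_threshold: 0.7    # deleteriousness score at or above which missense is Dmis
min_ppi_score: 600     # STRING combined score; edges must exceed this strictly
loeuf_max: 0.35        # constraint filter: LOEUF strictly below this
tier_cutoffs: [0.05, 0.1, 0.2]   # strong / possible / suggestive FDR tiers
n_downsample_iter: 2000
n_perm_network: 2000
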