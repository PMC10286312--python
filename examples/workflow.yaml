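# Example workflow configuration for the `tkreceptor` CLI.
#
#   tkreceptor run -c examples/workflow.yaml
#
# generates synthetic calibration/validation data from the default
# best-fit parameters, calibrates the TK-receptor model, profiles the
# identified parameters, fits a synthetic binding assay, and writes a
# summary report with BCF threshold crossings.

outdir: tkreceptor_out
seed: 1
cv: 0.05                # multiplicative noise CV of the TK datasets
binding_cv: 0.10        # noise CV of the binding assay
n_starts: 16            # optimizer multi-starts (Latin hypercube)
error_scale: log        # Gaussian likelihood on log concentrations

# generating ("true") parameters for the synthetic stage
generating:
  k_u: 10.6             # uptake rate, L/kg/d
  k_e: 5.2              # elimination rate, 1/d
  k_on: 200.0           # association rate, kg/umol/d
  B_max: 25.0           # binding capacity, umol/kg_MP
binding_generating:
  b_max: 5.7            # umol/kg_MP
  k_d: 0.41             # nM

profile_params: [k_u, k_e, B_max]
thresholds: [2000.0, 5000.0]   # regulatory BCF criteria, L/kg
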