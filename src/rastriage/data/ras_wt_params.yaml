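# Default wild-type parameterisation of the Ras activation-cycle model.
#
# PLACEHOLDER VALUES: these are representative numbers assembled from
# typical published Ras enzymology (order-of-magnitude realistic for
# SOS-catalysed exchange, p120GAP-catalysed hydrolysis, intrinsic rates
# and Ras-RBD effector binding).  Substitute measured values by passing
# your own copy of this file to `load_params` / `rastriage simulate`.
#
# Units: abundances in molecules within `volume_litres`; unimolecular
# rates in 1/s; kon_* in 1/(M*s).  The GEF/GAP off-rates below already
# include a 10-fold decrease relative to solution values, accounting for
# membrane co-localisation of the enzymes with Ras.

volume_litres: 1.0e-14

abundances:
  ras_total: 6000      # ~1 uM total H/K/N-Ras
  gef_total: 120       # ~20 nM SOS1
  gap_total: 300       # ~50 nM RASA1
  eff_total: 1200      # ~0.2 uM RAF1 + BRAF

rates:
  k_gef: 3.9                 # GEF-catalysed GDP release, 1/s
  k_gap: 19.0                # GAP-catalysed GTP hydrolysis, 1/s
  k_gdp_exch_intr: 1.0e-4    # intrinsic nucleotide dissociation, 1/s
  k_gtp_hydr_intr: 2.0e-4    # intrinsic GTP hydrolysis, 1/s
  kon_gef: 1.0e+7            # 1/(M*s)
  koff_gef: 0.3              # 1/s (10-fold decreased, see header)
  kon_gap: 1.0e+7            # 1/(M*s)
  koff_gap: 1.0              # 1/s (10-fold decreased, see header)
  kon_eff: 4.5e+7            # 1/(M*s)
  koff_eff: 5.4              # 1/s  -> K_D(EFF) = 120 nM

# Mutant fold changes relative to wild type (dimensionless, > 0).
# PLACEHOLDER VALUES in the measured direction of effect: the oncogenic
# reference is GAP-insensitive with slowed intrinsic hydrolysis; the
# compensatory variants add a loss of GEF-catalysed activation on top of
# GAP loss (the partly compensatory germline mechanism).
variants:
  oncogenic_reference:
    gap: 0.001
    intrinsic_hydrolysis: 0.2
  gap_loss:
    gap: 0.02
    intrinsic_hydrolysis: 0.2
  compensatory:
    gef: 0.4
    gap: 0.02
    intrinsic_hydrolysis: 0.2
  compensatory_mild:
    gef: 0.6
    gap: 0.05
    intrinsic_hydrolysis: 0.5
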