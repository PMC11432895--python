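# Default health-economic parameter set -- PLACEHOLDER VALUES.
#
# Transition probabilities, state costs and utilities below are plausible
# placeholders chosen to satisfy every structural invariant of the model
# (row-stochastic transitions, absorbing death, undiagnosed progression at
# least as fast as diagnosed, utilities in [0, 1]).  They are NOT the
# study-specific inputs of any published evaluation; to reproduce a
# published base case, transcribe its supplementary parameter tables over
# the fields below.
#
# Units: transition entries are annual probabilities; costs GBP per year
# (state_costs) or GBP one-off (test/referral); utilities QALY-weights per
# year.  Transition rows list only outgoing moves; the stay-probability is
# the residual.  Background (non-liver) mortality is applied on top of the
# disease transitions.

prevalence:            # screening-population case mix
  MLD: 0.83            # mild or no liver disease
  SLD: 0.14            # significant/advanced fibrosis, not cirrhotic
  CC: 0.03             # compensated cirrhosis

transitions:
  MLD:
    SLD_fn: 0.02       # incident disease arises undetected post-screening
  SLD_dx:
    CC_dx: 0.02        # managed disease progresses more slowly
    DEAD: 0.002
  SLD_fn:
    CC_fn: 0.045
    DEAD: 0.004
  CC_dx:
    DC: 0.04
    HCC: 0.015
    DEAD: 0.02
  CC_fn:
    DC: 0.07
    HCC: 0.025
    DEAD: 0.03
  DC:
    HCC: 0.02
    LT: 0.03
    DEAD: 0.13
  HCC:
    LT: 0.02
    DEAD: 0.25
  LT:
    DEAD: 0.04

state_costs:           # GBP per year of state occupancy
  MLD: 100.0
  SLD_dx: 800.0        # diagnosed disease carries management/clinic costs
  SLD_fn: 150.0
  CC_dx: 3500.0        # cirrhosis surveillance (endoscopy, HCC screening)
  CC_fn: 400.0
  DC: 12000.0
  HCC: 15000.0
  LT: 20000.0
  DEAD: 0.0

state_utilities:       # QALY-weight per year
  MLD: 0.85
  SLD_dx: 0.82
  SLD_fn: 0.82
  CC_dx: 0.75
  CC_fn: 0.75
  DC: 0.50
  HCC: 0.45
  LT: 0.60
  DEAD: 0.0

strategies:            # first-tier operating points and per-person test cost
  US_LFTS: {sensitivity: 0.35, specificity: 0.65, test_cost: 60.0}
  FIB4:    {sensitivity: 0.62, specificity: 0.80, test_cost: 5.0}
  NFS:     {sensitivity: 0.60, specificity: 0.70, test_cost: 5.0}
  BIMAST:  {sensitivity: 0.94, specificity: 0.44, test_cost: 2.0}
  ELF:     {sensitivity: 0.46, specificity: 0.85, test_cost: 50.0}
  TE:      {sensitivity: 1.00, specificity: 1.00, test_cost: 70.0}
  SOC:     {sensitivity: 0.175, specificity: 0.825, test_cost: 0.0}

referral_cost: 400.0          # GBP per screen-positive specialist work-up
background_mortality: 0.015   # annual non-liver death probability
discount_rate: 0.035          # per year, costs and outcomes
horizon: 40                   # years (lifetime)
cohort_size: 287              # persons
cet: 20000.0                  # GBP/QALY cost-effectiveness threshold
half_cycle_correction: false

psa_distributions:            # beta for probabilities/utilities, gamma for costs
  state_costs.DC:          {dist: gamma, shape: 16.0, scale: 750.0}
  state_costs.HCC:         {dist: gamma, shape: 25.0, scale: 600.0}
  state_utilities.DC:      {dist: beta, alpha: 10.0, beta: 10.0}
  state_utilities.MLD:     {dist: beta, alpha: 85.0, beta: 15.0}
  transitions.MLD.SLD_fn:  {dist: beta, alpha: 4.0, beta: 196.0}
  referral_cost:           {dist: gamma, shape: 25.0, scale: 16.0}
  background_mortality:    {dist: beta, alpha: 3.0, beta: 197.0}
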