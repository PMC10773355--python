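# Default base-case parameters for the DVA identification-and-referral
# cost-utility model: six-month transition probabilities, utilities and
# societal costs with their 95% limits and distribution families.
#
# Costs are 2019/2020 GBP. The child abuse cost defaults to the 2018
# figure (1950); an inflated 2019 variant (1969) may be substituted, in
# which case the weighted abuse cost becomes 0.8*4858 + 0.2*1969 = 4280.2.

run:
  cycles: 20            # six-month cycles; cycle 1 holds the initial distribution
  cohort: 10000
  discount_annual: 0.035
  lambda: 20000         # willingness to pay, GBP per QALY

weights:
  child_share: 0.20
  adult_female_share: 0.40
  adult_male_share: 0.40

transitions:
  shared:
    prevalence_all_ages:          {family: beta,    base: 0.055,  lower: 0.038,  upper: 0.106}
    start_id_advocate:            {family: uniform, base: 0.003,  lower: 0.0,    upper: 0.0066}
    start_id_no_advocate:         {family: uniform, base: 0.033,  lower: 0.0,    upper: 0.0660}
    no_abuse_to_unidentified:     {family: dirichlet_row, base: 0.0037, lower: 0.0004, upper: 0.0106}
    no_abuse_to_dead:             {family: dirichlet_row, base: 0.0052, lower: 0.0027, upper: 0.0087}
    id_advocate_to_no_abuse:      {family: dirichlet_row, base: 0.1408, lower: 0.0707, upper: 0.2301}
    id_advocate_to_dead:          {family: dirichlet_row, base: 0.0052, lower: 0.0,    upper: 0.0299}
    id_no_advocate_to_no_abuse:   {family: dirichlet_row, base: 0.0781, lower: 0.0136, upper: 0.1912}
    id_no_advocate_to_dead:       {family: dirichlet_row, base: 0.0052, lower: 0.0,    upper: 0.0424}
    unidentified_to_no_abuse:     {family: dirichlet_row, base: 0.0500, lower: 0.0412, upper: 0.0596}
    unidentified_to_dead:         {family: dirichlet_row, base: 0.0055, lower: 0.0029, upper: 0.0091}
  intervention:
    unidentified_to_id_no_advocate: {family: dirichlet_row, base: 0.0374, lower: 0.0298, upper: 0.0458}
    unidentified_to_id_advocate:    {family: dirichlet_row, base: 0.0312, lower: 0.0243, upper: 0.0390}
  control:
    unidentified_to_id_no_advocate: {family: dirichlet_row, base: 0.0091, lower: 0.0055, upper: 0.0135}
    unidentified_to_id_advocate:    {family: dirichlet_row, base: 0.0226, lower: 0.0168, upper: 0.0293}

utilities:
  no_abuse:
    women:    {family: beta, base: 0.850, lower: 0.840, upper: 0.860}
    men:      {family: beta, base: 0.850, lower: 0.840, upper: 0.860}
    children: {family: beta, base: 0.950, lower: 0.940, upper: 0.959}
  unidentified:
    women:    {family: beta, base: 0.656, lower: 0.522, upper: 0.749}
    men:      {family: beta, base: 0.626, lower: 0.500, upper: 0.744}
    children: {family: beta, base: 0.801, lower: 0.623, upper: 0.932}
  id_advocate:
    women:    {family: beta, base: 0.659, lower: 0.518, upper: 0.782}
    men:      {family: beta, base: 0.701, lower: 0.555, upper: 0.828}
    children: {family: beta, base: 0.804, lower: 0.625, upper: 0.935}
  id_no_advocate:
    women:    {family: beta, base: 0.656, lower: 0.522, upper: 0.749}
    men:      {family: beta, base: 0.626, lower: 0.500, upper: 0.744}
    children: {family: beta, base: 0.801, lower: 0.623, upper: 0.932}

costs:
  intervention_cost_per_patient_per_cycle: {family: gamma, base: 0.75, lower: 0.02, upper: 2.73}
  onward_referral_cost_once:               {family: gamma, base: 658,  lower: 11,   upper: 1908}
  abuse_cost_weighted_per_cycle:           {family: gamma, base: 4276, lower: 108,  upper: 15774}
  abuse_cost_adult_per_cycle:              {family: gamma, base: 4858, lower: 123,  upper: 17919}
  abuse_cost_child_per_cycle:              {family: gamma, base: 1950, lower: 1000, upper: 2500}
  cost_multiplier_id_advocate:             {family: gamma, base: 1.0,  lower: 0.75, upper: 1.25}
  cost_multiplier_id_no_advocate:          {family: gamma, base: 1.0,  lower: 0.9,  upper: 1.1}
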