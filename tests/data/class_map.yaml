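# Checked-in fixture: canonical grouping of the 10 policies into 6 classes
# (4 restrictive + 2 permissive), class -> combination membership, and the
# signs of the most-restrictive contrast.
policy_to_class:
  bc_dealer: background_checks
  bc_private: background_checks
  possess_under18: minimum_age
  purchase_under20: minimum_age
  wait_24h: waiting_periods
  wait_7day: waiting_periods
  child_access_storage: child_access
  shall_issue: concealed_carry
  permitless_carry: concealed_carry
  stand_your_ground: stand_your_ground
class_to_combination:
  background_checks: purchase_and_possession
  minimum_age: purchase_and_possession
  waiting_periods: purchase_and_possession
  child_access: use_and_storage
  concealed_carry: use_and_storage
  stand_your_ground: use_and_storage
most_restrictive_sign:
  bc_dealer: 1
  bc_private: 1
  possess_under18: 1
  purchase_under20: 1
  wait_24h: 1
  wait_7day: 1
  child_access_storage: 1
  shall_issue: -1
  permitless_carry: -1
  stand_your_ground: -1
restrictive_classes: [background_checks, minimum_age, waiting_periods, child_access]
permissive_classes: [concealed_carry, stand_your_ground]
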