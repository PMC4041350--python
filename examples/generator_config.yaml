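# Example generator configuration for `hdsslink generate --config ...`.
# Any omitted key keeps its default (shown here). Probabilities are per
# draw; completeness values are the probability a field is present.

n_registry: 5000
n_clinic: 1000
overlap_fraction: 0.6          # share of clinic patients with a registry counterpart
mean_household_size: 5.0

# identifier corruption applied to true-match clinic records
typo_rate: 0.25                # one random character edit per name
phonetic_swap_rate: 0.30       # phonetically plausible spelling rewrite
surname_change_rate_female: 0.20  # married name differs from registry surname
dob_error_rate: 0.30           # one date-of-birth component misreported
village_change_rate: 0.15      # different village reported at the clinic

# corruption-rate modifiers tied to person attributes
covariate_effects:
  age_slope_per_decade_over_50: 0.5
  other_ethnicity_name_multiplier: 1.75

# per-source field completeness; defaults mirror the observed completeness
# of each identifier in an HDSS register vs. a clinic register
missingness:
  registry:
    other_first_name: 0.3557
    hh_member_first_name: 0.9848
    hh_member_surname: 0.9848
    national_id: 0.6714
    phone: 0.3748
  clinic:
    other_first_name: 0.0614
    sex: 0.9995
    village: 0.8117
    hh_member_first_name: 0.7729
    hh_member_surname: 0.7660
    national_id: 0.0155
    phone: 0.2667

reference_year: 2010           # age = reference_year - birth_year
seed: 0
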