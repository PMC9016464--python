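# Coefficient tables for the composite fibrosis scores.
#
# Each block carries a provenance string naming the developer publication the
# values were transcribed from. Categorical bands use closed lower bounds
# (value >= lower belongs to the band), matching the source definitions.
version: 1

apri:
  provenance: >-
    Wai et al., Hepatology 2003. AST upper limit of normal is not fixed by the
    score definition; 40 U/L is the conventional default and is configurable.
  ast_uln: 40.0

nfs:
  provenance: >-
    Angulo et al., Hepatology 2007 (NAFLD fibrosis score). Albumin in g/dL,
    platelets in 10^9/L.
  intercept: -1.675
  age: 0.037
  bmi: 0.094
  ifg_or_diabetes: 1.13
  ast_alt_ratio: 0.99
  platelets: -0.013
  albumin: -0.66

hfs:
  provenance: >-
    Ampuero et al., Clin Gastroenterol Hepatol 2020 (Hepamet fibrosis score).
    Logistic model on categorical bands; HFS = 1/(1 + exp(linear predictor)).
    The HOMA-IR bands are scored additively alongside the diabetes term; the
    interplay between the two is ambiguous in secondary sources and recorded
    here as implemented.
  intercept: 5.390
  # subtracted when the band applies
  age_45_to_64: 0.986
  age_ge_65: 1.719
  male: 0.875
  ast_35_to_69: 0.896
  ast_ge_70: 2.126
  albumin_4_to_4_49: 0.027
  albumin_lt_4: 0.897
  homa_2_to_3_99: 0.899
  homa_ge_4: 1.497
  diabetes: 2.184
  platelets_155_to_219: 0.882
  platelets_lt_155: 2.233

adapt:
  provenance: >-
    Daniels et al., Hepatology 2019. ADAPT = exp(log10(age x PRO-C3 /
    sqrt(platelets)) + diabetes), diabetes coded 0/1.
  diabetes: 1.0

fibc3:
  provenance: >-
    Boyle et al., JHEP Reports 2019 (FIB-C3). Linear model; platelets in
    10^9/L, PRO-C3 in ng/mL.
  intercept: -5.939
  age: 0.053
  bmi: 0.076
  diabetes: 1.614
  platelets: -0.009
  pro_c3: 0.071

mack3:
  provenance: >-
    SYNTHETIC / RECONSTRUCTED. The MACK-3 developer coefficients (Boursier et
    al., Aliment Pharmacol Ther 2018) could not be transcribed from an
    authoritative source; this logistic surrogate uses the correct inputs
    (HOMA-IR, AST, CK-18 M30), functional form and sign structure, calibrated
    to the published operating range (median ~0.10 in an obese biopsy cohort;
    decision cutoffs 0.134 and 0.549 both attainable).
  intercept: -6.0
  homa_ir: 0.30
  ast: 0.04
  ck18_m30: 0.009
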