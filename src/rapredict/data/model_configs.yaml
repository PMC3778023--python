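# The five standard prediction-model configurations.
# SNP / HLA_SNP models use the 31-SNP set; HLA_SNP_smoking uses the 28 SNPs
# genotyped in both source cohorts.  Models incorporating ever-smoking are
# evaluated in males only.
prevalence: 0.008
ci_level: 0.95

factor_sets:
  hla_all:
    ["*01", "*01:01", "*03", "*03:01", "*04", "*04:01", "*04:04", "*04:05",
     "*04:08", "*07", "*07:01", "*08", "*08:01", "*10", "*10:01", "*11",
     "*11:01", "*11:04", "*13", "*13:01", "*13:02", "*14", "*14:01", "*15",
     "*15:01"]
  snp_31:
    [rs2476601, rs6920220, rs6859219, rs4810485, rs3087243, rs5029937,
     rs706778, rs3761847, rs7574865, rs934734, rs3093023, rs13315591,
     rs26232, rs13031237, rs10865035, rs4750316, rs10488631, rs3890745,
     rs11586238, rs2736340, rs1980422, rs548234, rs2812378, rs10919563,
     rs1678542, rs540386, rs12746613, rs394581, rs10499194, rs2104286,
     rs3218253]
  snp_28:
    [rs2476601, rs6920220, rs4810485, rs3087243, rs5029937, rs706778,
     rs3761847, rs7574865, rs3093023, rs13315591, rs26232, rs13031237,
     rs10865035, rs4750316, rs3890745, rs11586238, rs2736340, rs1980422,
     rs548234, rs2812378, rs10919563, rs1678542, rs540386, rs12746613,
     rs394581, rs10499194, rs2104286, rs3218253]

models:
  SNP:
    factors: ["@snp_31"]
  HLA:
    factors: ["@hla_all"]
  HLA_SNP:
    factors: ["@hla_all", "@snp_31"]
  HLA_smoking:
    factors: ["@hla_all", ever_smoking_male]
    sex_restriction: males_only
  HLA_SNP_smoking:
    factors: ["@hla_all", "@snp_28", ever_smoking_male]
    sex_restriction: males_only
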