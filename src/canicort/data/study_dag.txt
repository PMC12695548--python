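# Reconstructed causal DAG for hair cortisol (HCC) in dogs with obesity.
# The study's full edge list is not public; this graph is constrained so
# that its minimal backdoor adjustment sets reproduce the study's model
# specifications:
#   age -> hcc adjusted for {breed}; sex, breed, season unadjusted;
#   coat adjusted for {breed}; comorbidity adjusted for {age, breed, sex};
#   body_fat adjusted for {age, breed, sex, comorbidity};
#   weight_loss_success and visit unidentifiable (unmeasured owner and
#   environmental factors, including pandemic effects, confound them with
#   body fat).

observed: age sex breed coat season comorbidity body_fat weight_loss_success visit hcc
unobserved: owner_environment

breed -> age
breed -> coat
breed -> comorbidity
breed -> body_fat
breed -> hcc
age -> comorbidity
age -> body_fat
age -> hcc
sex -> comorbidity
sex -> body_fat
sex -> hcc
comorbidity -> body_fat
comorbidity -> hcc
coat -> hcc
season -> hcc
body_fat -> hcc
owner_environment -> body_fat
owner_environment -> weight_loss_success
owner_environment -> visit
weight_loss_success -> body_fat
visit -> body_fat

outcome: hcc
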