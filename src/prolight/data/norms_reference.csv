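comparator,scale_id,sex,age_lo,age_hi,mean,sd,n
lymphoma_cohort,physical_functioning,pooled,,,79.4,21,876
lymphoma_cohort,emotional_functioning,pooled,,,82.8,21,876
lymphoma_cohort,cognitive_functioning,pooled,,,82.4,23,876
lymphoma_cohort,social_functioning,pooled,,,84.4,24,876
lymphoma_cohort,global_qol,pooled,,,74.0,20,876
lymphoma_cohort,fatigue,pooled,,,28.9,27,876
lymphoma_cohort,tingling,pooled,,,17.0,29,876
lymphoma_cohort,hads_anxiety,pooled,,,4.4,3.8,876
lymphoma_cohort,hads_depression,pooled,,,4.7,3.8,876
normative_population,physical_functioning,pooled,,,90.5,15,1852
normative_population,emotional_functioning,pooled,,,87.9,17,1852
normative_population,cognitive_functioning,pooled,,,92.5,14,1852
normative_population,social_functioning,pooled,,,93.6,16,1852
normative_population,global_qol,pooled,,,77.6,17,1852
normative_population,fatigue,pooled,,,17.0,20,1852
normative_population,hads_anxiety,pooled,,,3.6,3.2,1852
normative_population,hads_depression,pooled,,,3.6,3.2,1852
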