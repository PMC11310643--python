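funder,activity,input_type,amount_usd,arm_scope
global_fund,diagnosis_treatment,consumables,70871,both_arms
global_fund,diagnosis_treatment,personnel,3800,both_arms
global_fund,iec,consumables,64754,both_arms
global_fund,iec,personnel,254432,both_arms
global_fund,program_management,consumables,2500,both_arms
expertise_france,iec,consumables,125767,intervention_only
expertise_france,iec,personnel,34314,intervention_only
expertise_france,program_management,personnel,3099,intervention_only
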