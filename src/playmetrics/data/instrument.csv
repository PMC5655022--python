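item_id,area,scale_min,scale_max,description
communication_01,communication,1,5,
communication_02,communication,1,5,
communication_03,communication,1,5,
communication_04,communication,1,5,
communication_05,communication,1,5,
communication_06,communication,1,5,
communication_07,communication,1,5,
communication_08,communication,1,5,
communication_09,communication,1,5,
communication_10,communication,1,5,
communication_11,communication,1,5,
communication_12,communication,1,5,
communication_13,communication,1,5,
communication_14,communication,1,5,
fine_motor_01,fine_motor,1,5,
fine_motor_02,fine_motor,1,5,
fine_motor_03,fine_motor,1,5,
fine_motor_04,fine_motor,1,5,
fine_motor_05,fine_motor,1,5,
fine_motor_06,fine_motor,1,5,
fine_motor_07,fine_motor,1,5,
fine_motor_08,fine_motor,1,5,
gross_motor_01,gross_motor,1,5,
gross_motor_02,gross_motor,1,5,
gross_motor_03,gross_motor,1,5,
gross_motor_04,gross_motor,1,5,
gross_motor_05,gross_motor,1,5,
gross_motor_06,gross_motor,1,5,
gross_motor_07,gross_motor,1,5,
gross_motor_08,gross_motor,1,5,
gross_motor_09,gross_motor,1,5,
following_instructions_01,following_instructions,1,5,
following_instructions_02,following_instructions,1,5,
self_reliance_01,self_reliance,1,5,
self_reliance_02,self_reliance,1,5,
self_reliance_03,self_reliance,1,5,
self_reliance_04,self_reliance,1,5,
self_reliance_05,self_reliance,1,5,
self_reliance_06,self_reliance,1,5,
social_emotional_01,social_emotional,1,5,
social_emotional_02,social_emotional,1,5,
social_emotional_03,social_emotional,1,5,
social_emotional_04,social_emotional,1,5,
social_emotional_05,social_emotional,1,5,
social_emotional_06,social_emotional,1,5,
social_emotional_07,social_emotional,1,5,
social_emotional_08,social_emotional,1,5,
social_emotional_09,social_emotional,1,5,
stereotypical_01,stereotypical,1,5,
stereotypical_02,stereotypical,1,5,
stereotypical_03,stereotypical,1,5,
stereotypical_04,stereotypical,1,5,
stereotypical_05,stereotypical,1,5,
stimulation_reaction_01,stimulation_reaction,1,5,
stimulation_reaction_02,stimulation_reaction,1,5,
stimulation_reaction_03,stimulation_reaction,1,5,
stimulation_reaction_04,stimulation_reaction,1,5,
stimulation_reaction_05,stimulation_reaction,1,5,
stimulation_reaction_06,stimulation_reaction,1,5,
attention_01,attention,1,5,
attention_02,attention,1,5,
attention_03,attention,1,5,
attention_04,attention,1,5,
attention_05,attention,1,5,
challenging_01,challenging,1,5,
challenging_02,challenging,1,5,
challenging_03,challenging,1,5,
challenging_04,challenging,1,5,
challenging_05,challenging,1,5,
challenging_06,challenging,1,5,
challenging_07,challenging,1,5,
challenging_08,challenging,1,5,
challenging_09,challenging,1,5,
challenging_10,challenging,1,5,
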