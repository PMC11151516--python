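term,domains,construct
fear,negative_valence,acute threat
panic,negative_valence,acute threat
worry,negative_valence,potential threat
anxiety,negative_valence,potential threat
stress,negative_valence,sustained threat
abuse,negative_valence,sustained threat
suicidal,negative_valence,loss
aggression,negative_valence|social_processes,frustrative non-reward
reward,positive_valence,reward valuation
craving,positive_valence,reward seeking
alcohol,positive_valence,consummatory behavior
anhedonia,positive_valence,reduced behavioral activation
motivation,positive_valence,reward valuation
attention,cognitive,attention
memory,cognitive,declarative memory
concentration,cognitive,cognitive control
guilt,social_processes,self-perception
shame,social_processes,self-perception
attachment,social_processes,affiliation and attachment
distrust,social_processes,perception of others
sleep,arousal_regulatory,sleep-wakefulness
insomnia,arousal_regulatory,sleep-wakefulness
nightmare,arousal_regulatory,sleep-wakefulness
startle,arousal_regulatory,arousal
hyperarousal,arousal_regulatory,arousal
hallucination,sensorimotor,perception
tremor,sensorimotor,motor action
agitation,sensorimotor,motor action
psychomotor,sensorimotor,motor action
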