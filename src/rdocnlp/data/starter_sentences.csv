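id,text,domains,construct,provenance
nv-001,Patient is stressed and refuses psychotherapy,negative_valence,sustained threat,artifact
nv-002,Reports intense fear and panic when reminded of the assault,negative_valence,acute threat,artifact
nv-003,Expresses persistent worry about harm coming to her children,negative_valence,potential threat,artifact
nv-004,Endorses a history of emotional abuse and ongoing suicidal thoughts,negative_valence,sustained threat,artifact
nv-005,Episodes of reactive aggression toward coworkers after minor setbacks,negative_valence,frustrative non-reward,artifact
pv-001,Reports strong craving for alcohol since the last visit,positive_valence,reward seeking,artifact
pv-002,Describes anhedonia and little interest in previously enjoyable activities,positive_valence,reduced behavioral activation,artifact
pv-003,Motivation for work and hobbies has declined markedly,positive_valence,reward valuation,artifact
pv-004,Drinks alcohol daily to feel any sense of reward,positive_valence,consummatory behavior,artifact
cg-001,Attention wanders during conversation and tasks are left unfinished,cognitive,attention,artifact
cg-002,Patient complains of poor memory for recent events,cognitive,declarative memory,artifact
cg-003,Concentration is impaired at work and while driving,cognitive,cognitive control,artifact
cg-004,Unable to sustain attention long enough to finish reading a page,cognitive,attention,artifact
sp-001,Expresses profound guilt about surviving the accident,social_processes,self-perception,artifact
sp-002,Feels shame when discussing the event with family,social_processes,self-perception,artifact
sp-003,Attachment to her children feels distant and strained,social_processes,affiliation and attachment,artifact
sp-004,Voices distrust of close friends and avoids social contact,social_processes,perception of others,artifact
ar-001,Patient sleeps poorly and wakes several times each night,arousal_regulatory,sleep-wakefulness,artifact
ar-002,Reports insomnia and vivid nightmares most nights,arousal_regulatory,sleep-wakefulness,artifact
ar-003,Startles easily at loud noises in the clinic,arousal_regulatory,arousal,artifact
ar-004,Chronic hyperarousal with a racing heart at bedtime,arousal_regulatory,arousal,artifact
sm-001,Reports auditory hallucinations that worsen under pressure,sensorimotor,perception,artifact
sm-002,A fine tremor of both hands is evident on examination,sensorimotor,motor action,artifact
sm-003,Marked psychomotor agitation observed during the interview,sensorimotor,motor action,artifact
sm-004,Tremors worsen when she reaches for objects,sensorimotor,motor action,artifact
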