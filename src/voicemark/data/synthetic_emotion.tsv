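rage	Anger
furious	Anger
irritated	Anger
resent	Anger
mad	Anger
await	Anticipation
expect	Anticipation
plan	Anticipation
eager	Anticipation
soon	Anticipation
gross	Disgust
nasty	Disgust
sicken	Disgust
revolt	Disgust
loathe	Disgust
afraid	Fear
scared	Fear
dread	Fear
panic	Fear
terror	Fear
delight	Joy
cheer	Joy
glad	Joy
laugh	Joy
smile	Joy
grief	Sadness
sorrow	Sadness
gloom	Sadness
mourn	Sadness
weep	Sadness
sudden	Surprise
shock	Surprise
startle	Surprise
amaze	Surprise
unexpected	Surprise
rely	Trust
faith	Trust
depend	Trust
honest	Trust
loyal	Trust
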