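calm	0.6	Positive
hope	0.8	Positive
happy	0.9	Positive
better	0.5	Positive
good	0.7	Positive
relief	0.6	Positive
stable	0.5	Positive
enjoy	0.8	Positive
grateful	0.7	Positive
improve	0.6	Positive
peace	0.7	Positive
confident	0.8	Positive
tired	-0.6	Negative
pain	-0.8	Negative
sad	-0.9	Negative
worry	-0.7	Negative
bad	-0.7	Negative
lonely	-0.8	Negative
hopeless	-0.9	Negative
cry	-0.6	Negative
upset	-0.7	Negative
angry	-0.8	Negative
hurt	-0.7	Negative
restless	-0.5	Negative
maybe	0.0	Neutral
perhaps	0.0	Neutral
usual	0.0	Neutral
ordinary	0.0	Neutral
regular	0.0	Neutral
routine	0.0	Neutral
today	0.0	Non-opinionated
yesterday	0.0	Non-opinionated
morning	0.0	Non-opinionated
evening	0.0	Non-opinionated
umm	0.0	Not-a-word
uh	0.0	Not-a-word
hmm	0.0	Not-a-word
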