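# Minimal listener vocalizations; transcribed noise is mostly these.
mhm
uh-huh
hmm
mm
huh
yeah
mhmm
uh
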