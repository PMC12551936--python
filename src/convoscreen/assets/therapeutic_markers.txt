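# Markers of therapeutic conversation used by the deterministic mock
# classification backend and the synthetic session lexicon. Editable.
feeling
feelings
anxiety
anxious
depressed
depression
coping
therapy
therapist
session
goals
progress
emotions
stress
trauma
mindfulness
breathing
reframing
homework
journaling
relationship
boundaries
self-care
thoughts
triggers
support
strategies
medication
treatment
confidential
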