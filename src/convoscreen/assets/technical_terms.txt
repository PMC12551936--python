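# Bureaucratic / platform terms removed before frequent-noun extraction
# (scheduling, paperwork, telehealth plumbing). Editable.
appointment
schedule
scheduling
reschedule
form
forms
paperwork
consent
insurance
billing
copay
portal
zoom
audio
video
mic
microphone
recording
record
session-id
login
password
email
phone
call
voicemail
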