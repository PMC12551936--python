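# Markers of informal / non-clinical chatter for the mock backend and
# the synthetic informal lexicon. Editable.
dude
movie
game
pizza
party
weekend
football
beer
vacation
weather
traffic
shopping
concert
netflix
lol
hilarious
barbecue
gossip
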