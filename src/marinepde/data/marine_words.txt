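# Marine-related keyword list used to classify isolation-source strings.
# One case-insensitive substring per line; lines starting with '#' are ignored.
# The list is deliberately editable: keyword screens of free-text metadata are
# experience-based and should be tuned to the corpus at hand.
marine
sea
ocean
oceanic
seawater
saltwater
brackish
estuar
coastal
intertidal
tidal flat
mangrove
coral
sponge
kelp
macroalga
seaweed
hydrothermal
abyssal
hadal
pelagic
benthic
bathyal
fjord
lagoon
gulf of
mariculture
saltern
tide pool
beach
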