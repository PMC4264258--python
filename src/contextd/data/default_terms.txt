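# Default medical term list for the synthetic corpus generator.
koorts
hoest
sinusitis
pneumonie
diabetes
hypertensie
tinnitus
urineweginfecties
appendicitis
trombose
kanker
hoofdpijn
dyspnoe
astma
eczeem
migraine
anemie
artrose
depressie
bronchitis
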