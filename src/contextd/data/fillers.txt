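# Neutral filler vocabulary for the synthetic corpus generator.
# Deliberately disjoint from the shipped trigger lexicons, the default term
# list and the temporal-pattern vocabulary; no digits.
verder
vandaag
rustig
duidelijk
stabiel
beoordeling
controle
verloop
overleg
beleid
uitleg
besproken
gestart
vervolg
lichamelijk
onderzoek
normaal
beiderzijds
soepel
conform
afspraak
telefonisch
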