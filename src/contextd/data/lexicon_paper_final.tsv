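phrase	property	role	doc_types	max_scope_tokens	note
geen	negation	pre	*		most frequent negation trigger
niet	negation	pre	*		not
zonder	negation	pre	*		without
geen teken van	negation	pre	*		no sign of
geen aanwijzing voor	negation	pre	*		no indication for
geen aanwijzingen voor	negation	pre	*		no indications for
had nooit	negation	pre	*		variant of 'never had'
hadden nooit	negation	pre	*		variant of 'never had'
nooit gehad	negation	post	*		variant of 'never had'
uitgesloten	negation	post	*		ruled out
niet aangetoond	negation	post	*		not demonstrated
afwezig	negation	post	*		absent
niet minder	negation	pseudo	*		masks 'niet' (no fewer)
geen toename	negation	pseudo	*		masks 'geen' (no increase)
maar	negation	termination	*		but
behalve	negation	termination	*		except
behoudens	negation	termination	*		except for
status na	historical	pre	*		status after
voorgeschiedenis van	historical	pre	*		history of
doorgemaakte	historical	pre	*		past (adjectival)
in de voorgeschiedenis	historical	post	*		in the medical history
indien	hypothetical	pre	*		if
tenzij	hypothetical	pre	*		unless
moeder	experiencer	pre	*		mother
vader	experiencer	pre	*		father
broer	experiencer	pre	*		brother
zus	experiencer	pre	*		sister
ouders	experiencer	pre	*		parents
familie	experiencer	pre	*		family
familieanamnese	experiencer	pre	*		family history
grootmoeder	experiencer	pre	*		grandmother
grootvader	experiencer	pre	*		grandfather
tante	experiencer	pre	*		aunt
oom	experiencer	pre	*		uncle
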